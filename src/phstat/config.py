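"""YAML experiment configuration: validation and object construction.

A config file has sections ``chemistry / kinetics / plant / controller /
schedule`` plus a top-level ``seed``.  Unknown keys anywhere are rejected
so typos fail loudly.  Two scenarios ship with the package:

* ``chibio`` -- 12 mL, 1.2 g PET in 1x1 cm films, 1 M NaOH, tolerance 0.1;
* ``applikon`` -- 250 mL, 25 g PET in 2.5x2.5 cm films, 4 M NaOH,
  tolerance 0.05.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import yaml

from .chemistry import ProticSpecies, SolutionComposition, sodium_for_target_ph
from .controller import ControlSettings
from .kinetics import EnzymePool, FilmSubstrate
from .kinetics import ProductPool
from .plant import ProbeModel, PumpModel, ReactorState
from .experiment import Schedule

__all__ = [
    "RunConfig",
    "load_config",
    "config_from_dict",
    "packaged_config_names",
    "load_packaged_config",
]

_TOP_KEYS = {"seed", "chemistry", "kinetics", "plant", "controller", "schedule"}
_CHEM_KEYS = {"pKw", "initial_ph", "species"}
_SPECIES_KEYS = {"name", "pKa", "charge_fully_protonated", "concentration_M"}
_KIN_KEYS = {"film", "enzyme"}
_FILM_KEYS = {
    "n_films",
    "length_cm",
    "width_cm",
    "thickness_cm",
    "density_g_per_cm3",
    "repeat_unit_mass_g_per_mol",
}
_ENZ_KEYS = {
    "loading_mg_per_g",
    "surface_rate_constant",
    "deactivation_rate_per_h",
    "mhet_fraction",
    "mhet_conversion_rate_per_h",
    "bhet_fraction",
}
_PLANT_KEYS = {"volume_mL", "temperature_C", "probe", "pump", "acid_pump"}
_PROBE_KEYS = {"noise_sd", "resolution", "accuracy_band"}
_PUMP_KEYS = {"nominal_dose_uL", "dose_sd_uL"}
_CTRL_KEYS = {
    "target_ph",
    "tolerance",
    "cycle_time_s",
    "mode",
    "set_dose_volume_uL",
    "titrant_concentration_M",
    "max_added_volume_mL",
    "pump_line",
}
_SCHED_KEYS = {
    "duration_h",
    "measure_interval_s",
    "ui_report_interval_s",
    "kinetics_dt_s",
    "sample_events",
}


def _check_keys(section: dict, allowed: set, path: str) -> None:
    if not isinstance(section, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {path!r}: {', '.join(sorted(map(str, unknown)))}"
        )


@dataclass(frozen=True)
class RunConfig:
    """A fully validated experiment: built objects plus the raw dict."""

    seed: int
    state: ReactorState
    probe: ProbeModel
    pumps: tuple[PumpModel, ...]
    settings: ControlSettings
    schedule: Schedule
    initial_ph: float
    raw: dict
    digest: str

    @property
    def initial_pet_mass(self) -> float:
        return self.state.substrate.initial_mass

    @property
    def repeat_unit_mass(self) -> float:
        return self.state.substrate.repeat_unit_mass

    def log_metadata(self) -> dict:
        """Metadata embedded in the log so analysis is self-contained."""
        return {
            "config_digest": self.digest,
            "seed": self.seed,
            "target_ph": self.settings.target_ph,
            "tolerance": self.settings.tolerance,
            "set_dose_volume_uL": self.settings.set_dose_volume,
            "titrant_concentration_M": self.settings.titrant_concentration,
            "initial_pet_mass_g": self.initial_pet_mass,
            "repeat_unit_mass_g_per_mol": self.repeat_unit_mass,
            "volume_L": self.state.solution.volume,
        }


def config_from_dict(data: dict) -> RunConfig:
    """Validate a config mapping and build the simulation objects."""
    _check_keys(data, _TOP_KEYS, "<top level>")
    for required in ("chemistry", "kinetics", "plant", "controller", "schedule"):
        if required not in data:
            raise ValueError(f"missing config section {required!r}")
    seed = int(data.get("seed", 0))

    chem = data["chemistry"]
    _check_keys(chem, _CHEM_KEYS, "chemistry")
    species = []
    for i, spec in enumerate(chem.get("species", [])):
        _check_keys(spec, _SPECIES_KEYS, f"chemistry.species[{i}]")
        species.append(
            ProticSpecies(
                name=str(spec["name"]),
                pka_list=tuple(spec["pKa"]),
                charge_fully_protonated=int(spec.get("charge_fully_protonated", 0)),
                total_concentration=float(spec.get("concentration_M", 0.0)),
            )
        )
    names = {sp.name for sp in species}
    for needed in ("TPA", "MHET"):
        if needed not in names:
            raise ValueError(f"chemistry.species must include {needed!r}")

    plant = data["plant"]
    _check_keys(plant, _PLANT_KEYS, "plant")
    volume_L = float(plant["volume_mL"]) / 1000.0
    temperature = float(plant.get("temperature_C", 25.0))
    initial_ph = float(chem.get("initial_ph", 8.0))
    solution = SolutionComposition(
        species=tuple(species),
        sodium_total=0.0,
        volume=volume_L,
        temperature=temperature,
        pKw=float(chem.get("pKw", 13.997)),
    )
    sodium = sodium_for_target_ph(solution, initial_ph)
    solution = SolutionComposition(
        species=tuple(species),
        sodium_total=sodium,
        volume=volume_L,
        temperature=temperature,
        pKw=solution.pKw,
    )

    kin = data["kinetics"]
    _check_keys(kin, _KIN_KEYS, "kinetics")
    film = kin.get("film", {})
    _check_keys(film, _FILM_KEYS, "kinetics.film")
    substrate = FilmSubstrate(
        n_films=int(film.get("n_films", 35)),
        length=float(film.get("length_cm", 1.0)),
        width=float(film.get("width_cm", 1.0)),
        thickness=float(film.get("thickness_cm", 0.025)),
        density=float(film.get("density_g_per_cm3", 1.38)),
        repeat_unit_mass=float(film.get("repeat_unit_mass_g_per_mol", 192.17)),
    )
    enz = kin.get("enzyme", {})
    _check_keys(enz, _ENZ_KEYS, "kinetics.enzyme")
    enzyme = EnzymePool(
        loading=float(enz.get("loading_mg_per_g", 3.0)),
        surface_rate_constant=float(
            enz.get("surface_rate_constant", EnzymePool().surface_rate_constant)
        ),
        deactivation_rate=float(enz.get("deactivation_rate_per_h", 0.01)),
        mhet_fraction=float(enz.get("mhet_fraction", 0.10)),
        mhet_conversion_rate=float(enz.get("mhet_conversion_rate_per_h", 0.3)),
        bhet_fraction=float(enz.get("bhet_fraction", 0.0)),
    )

    probe_cfg = plant.get("probe", {})
    _check_keys(probe_cfg, _PROBE_KEYS, "plant.probe")
    probe = ProbeModel(
        noise_sd=float(probe_cfg.get("noise_sd", 0.02)),
        resolution=float(probe_cfg.get("resolution", 0.01)),
        accuracy_band=float(probe_cfg.get("accuracy_band", 0.1)),
    )

    ctrl = data["controller"]
    _check_keys(ctrl, _CTRL_KEYS, "controller")
    sched = data["schedule"]
    _check_keys(sched, _SCHED_KEYS, "schedule")
    schedule = Schedule(
        duration=float(sched["duration_h"]),
        measure_interval=float(sched.get("measure_interval_s", 30.0)),
        ui_report_interval=float(sched.get("ui_report_interval_s", 30.0)),
        kinetics_dt=float(sched.get("kinetics_dt_s", 10.0)),
        sample_events=tuple(
            (float(t), float(v)) for t, v in sched.get("sample_events", []) or []
        ),
    )
    settings = ControlSettings(
        target_ph=float(ctrl.get("target_ph", 8.0)),
        tolerance=float(ctrl.get("tolerance", 0.1)),
        cycle_time=float(ctrl.get("cycle_time_s", 90.0)),
        measure_interval=schedule.measure_interval,
        mode=str(ctrl.get("mode", "base_only")),
        set_dose_volume=float(ctrl.get("set_dose_volume_uL", 40.0)),
        titrant_concentration=float(ctrl.get("titrant_concentration_M", 1.0)),
        max_added_volume=float(ctrl.get("max_added_volume_mL", 15.0)),
        pump_line=int(ctrl.get("pump_line", 1)),
    )

    pump_cfg = plant.get("pump", {})
    _check_keys(pump_cfg, _PUMP_KEYS, "plant.pump")
    main_sign = "acid" if settings.mode == "acid_only" else "base"
    pumps = [
        PumpModel(
            nominal_dose=float(pump_cfg.get("nominal_dose_uL", 40.0)),
            dose_sd=float(pump_cfg.get("dose_sd_uL", 10.0)),
            titrant_concentration=settings.titrant_concentration,
            titrant_sign=main_sign,
        )
    ]
    if "acid_pump" in plant:
        acid_cfg = plant["acid_pump"]
        _check_keys(acid_cfg, _PUMP_KEYS, "plant.acid_pump")
        pumps.append(
            PumpModel(
                nominal_dose=float(acid_cfg.get("nominal_dose_uL", 40.0)),
                dose_sd=float(acid_cfg.get("dose_sd_uL", 10.0)),
                titrant_concentration=settings.titrant_concentration,
                titrant_sign="acid",
            )
        )

    state = ReactorState(
        solution=solution,
        substrate=substrate,
        products=ProductPool(),
        enzyme=enzyme,
    )
    digest = hashlib.sha256(
        yaml.safe_dump(data, sort_keys=True).encode()
    ).hexdigest()[:12]
    return RunConfig(
        seed=seed,
        state=state,
        probe=probe,
        pumps=tuple(pumps),
        settings=settings,
        schedule=schedule,
        initial_ph=initial_ph,
        raw=data,
        digest=digest,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML experiment configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return config_from_dict(data)


def packaged_config_names() -> list[str]:
    root = resources.files("phstat") / "configs"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_packaged_config(name: str) -> RunConfig:
    """Load one of the packaged scenarios (``chibio`` or ``applikon``)."""
    path = resources.files("phstat") / "configs" / f"{name}.yaml"
    if not path.is_file():
        raise ValueError(
            f"no packaged config {name!r}; available: {packaged_config_names()}"
        )
    data = yaml.safe_load(path.read_text())
    return config_from_dict(data)
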