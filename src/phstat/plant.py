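"""The simulated reactor plant: chemistry + kinetics + probe + pump.

Couples the speciation model to the film kinetics and exposes the same
observable surface a physical pH-controlled reactor exposes: a noisy,
quantized pH reading and a fixed-volume peristaltic dose with shot-to-shot
volume scatter.  All randomness flows through an explicit numpy Generator
so trajectories are reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chemistry import SolutionComposition, solve_ph
from .kinetics import EnzymePool, FilmSubstrate, ProductPool, step_kinetics

__all__ = [
    "ProbeModel",
    "PumpModel",
    "ReactorState",
    "advance",
    "read_ph",
    "deliver_dose",
    "withdraw_sample",
]

TPA = "TPA"
MHET = "MHET"


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ProbeModel:
    """pH probe readout model.

    noise_sd: Gaussian read noise (pH units).  resolution: quantization
    step of the reported value.  accuracy_band: the electrode's stated
    precision (metadata only; informs the recommended control tolerance,
    it is not applied to readings).
    """

    noise_sd: float = 0.02
    resolution: float = 0.01
    accuracy_band: float = 0.1

    def __post_init__(self) -> None:
        for field in ("noise_sd", "resolution", "accuracy_band"):
            if getattr(self, field) < 0.0:
                raise ValueError(f"{field} must be >= 0")

    def observe(self, true_ph: float, rng=None) -> float:
        """One reading of ``true_ph``: add noise, then quantize."""
        reading = true_ph
        if self.noise_sd > 0.0:
            reading += _as_rng(rng).normal(0.0, self.noise_sd)
        if self.resolution > 0.0:
            reading = round(reading / self.resolution) * self.resolution
        return reading


@dataclass(frozen=True)
class PumpModel:
    """A peristaltic pump line delivering a fixed titrant volume per activation."""

    nominal_dose: float = 40.0  # uL per activation
    dose_sd: float = 10.0  # uL shot-to-shot scatter
    titrant_concentration: float = 1.0  # mol/L
    titrant_sign: str = "base"  # "base" (NaOH) or "acid" (strong acid)

    def __post_init__(self) -> None:
        if not (self.nominal_dose > 0.0):
            raise ValueError("nominal_dose must be > 0")
        if self.dose_sd < 0.0:
            raise ValueError("dose_sd must be >= 0")
        if not (self.titrant_concentration >= 0.0):
            raise ValueError("titrant_concentration must be >= 0")
        if self.titrant_sign not in ("acid", "base"):
            raise ValueError("titrant_sign must be 'acid' or 'base'")


@dataclass(frozen=True)
class ReactorState:
    """Full ground-truth state of the simulated reactor.

    ``enzyme_mass_mg`` defaults to loading x initial PET mass and is carried
    explicitly so sample withdrawals dilute the enzyme consistently.
    """

    solution: SolutionComposition
    substrate: FilmSubstrate
    products: ProductPool
    enzyme: EnzymePool
    time: float = 0.0  # h
    volume_added: float = 0.0  # mL of titrant delivered to date
    enzyme_mass_mg: float | None = None

    def __post_init__(self) -> None:
        if self.volume_added < 0.0:
            raise ValueError("volume_added must be >= 0")
        if self.enzyme_mass_mg is None:
            object.__setattr__(
                self,
                "enzyme_mass_mg",
                self.enzyme.loading * self.substrate.initial_mass,
            )

    @property
    def enzyme_conc(self) -> float:
        """Bulk enzyme concentration in mg/mL."""
        return self.enzyme_mass_mg / (self.solution.volume * 1000.0)


def advance(state: ReactorState, dt: float) -> ReactorState:
    """Advance the reaction by ``dt`` hours (no dosing, no reading).

    Runs one kinetics step and refreshes the dissolved TPA/MHET totals of
    the solution from the product pool; pH stays implicit (recomputed on
    demand by :func:`read_ph` / :func:`phstat.chemistry.solve_ph`).
    """
    if not (dt > 0.0):
        raise ValueError("dt must be > 0")
    substrate, products, enzyme = step_kinetics(
        state.substrate, state.enzyme, state.products, state.enzyme_conc, dt
    )
    V = state.solution.volume
    solution = state.solution.with_species_conc(
        TPA, products.n_TPA / V
    ).with_species_conc(MHET, products.n_MHET / V)
    return replace(
        state,
        solution=solution,
        substrate=substrate,
        products=products,
        enzyme=enzyme,
        time=state.time + dt,
    )


def read_ph(state: ReactorState, probe: ProbeModel, rng=None) -> float:
    """One probe reading of the current reactor pH."""
    return probe.observe(solve_ph(state.solution), rng)


def deliver_dose(
    state: ReactorState, pump: PumpModel, rng=None
) -> tuple[ReactorState, float]:
    """Activate the pump once; return the new state and the actual volume (uL).

    The delivered volume is ``max(0, nominal + N(0, dose_sd))``.  All
    dissolved totals are diluted by the volume change; the titrant adds to
    ``sodium_total`` (base) or ``strong_acid_total`` (acid).
    """
    actual = pump.nominal_dose
    if pump.dose_sd > 0.0:
        actual += _as_rng(rng).normal(0.0, pump.dose_sd)
    actual = max(actual, 0.0)

    v = actual * 1e-6  # L
    sol = state.solution
    V_new = sol.volume + v
    f = sol.volume / V_new
    species = tuple(
        replace(sp, total_concentration=sp.total_concentration * f)
        for sp in sol.species
    )
    sodium = sol.sodium_total * f
    strong_acid = sol.strong_acid_total * f
    delta = pump.titrant_concentration * v / V_new
    if pump.titrant_sign == "base":
        sodium += delta
    else:
        strong_acid += delta
    solution = replace(
        sol,
        species=species,
        sodium_total=sodium,
        strong_acid_total=strong_acid,
        volume=V_new,
    )
    new_state = replace(
        state,
        solution=solution,
        volume_added=state.volume_added + actual / 1000.0,
    )
    return new_state, actual


def withdraw_sample(state: ReactorState, volume_mL: float) -> ReactorState:
    """Remove a liquid sample: dissolved species leave proportionally, solids stay."""
    v = volume_mL / 1000.0
    sol = state.solution
    if not (0.0 < v < sol.volume):
        raise ValueError("sample volume must be positive and below reactor volume")
    f = (sol.volume - v) / sol.volume
    products = ProductPool(
        n_TPA=state.products.n_TPA * f,
        n_MHET=state.products.n_MHET * f,
        n_BHET=state.products.n_BHET * f,
        n_EG=state.products.n_EG * f,
    )
    solution = replace(sol, volume=sol.volume - v)  # concentrations unchanged
    return replace(
        state,
        solution=solution,
        products=products,
        enzyme_mass_mg=state.enzyme_mass_mg * f,
    )
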