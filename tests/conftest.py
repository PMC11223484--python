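import copy

import pytest
import yaml
from importlib import resources

from phstat import experiment
from phstat.chemistry import (
    PHOSPHATE_PKAS,
    ProticSpecies,
    SolutionComposition,
    sodium_for_target_ph,
)
from phstat.config import config_from_dict


def phosphate(conc: float = 0.1, sodium: float = 0.0, **kw) -> SolutionComposition:
    return SolutionComposition(
        species=(ProticSpecies("phosphate", PHOSPHATE_PKAS, 0, conc),),
        sodium_total=sodium,
        **kw,
    )


def buffer_at_ph(target: float = 8.0, conc: float = 0.1) -> SolutionComposition:
    sol = phosphate(conc)
    return phosphate(conc, sodium=sodium_for_target_ph(sol, target))


@pytest.fixture(scope="session")
def chibio_dict() -> dict:
    text = (resources.files("phstat") / "configs" / "chibio.yaml").read_text()
    return yaml.safe_load(text)


@pytest.fixture(scope="session")
def chibio_run(chibio_dict):
    """One full 72 h closed-loop run of the packaged small-scale scenario."""
    cfg = config_from_dict(copy.deepcopy(chibio_dict))
    result = experiment.run(
        cfg.state, cfg.probe, cfg.pumps, cfg.settings, cfg.schedule, rng_seed=11
    )
    return cfg, result


@pytest.fixture(scope="session")
def exact_dose_run(chibio_dict):
    """12 h run with noise-free pump dosing and the MHET channel active.

    Used for titrant-stoichiometry cross checks, where pump scatter would
    otherwise blur the controller's book-keeping against the plant.
    """
    d = copy.deepcopy(chibio_dict)
    d["plant"]["pump"]["dose_sd_uL"] = 0.0
    d["schedule"]["duration_h"] = 12.0
    cfg = config_from_dict(d)
    result = experiment.run(
        cfg.state, cfg.probe, cfg.pumps, cfg.settings, cfg.schedule, rng_seed=13
    )
    return cfg, result


# re-export as plain helpers for direct import in test modules
__all__ = ["phosphate", "buffer_at_ph"]
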