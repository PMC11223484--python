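"""Quantitative read-outs of a pH-stat PET hydrolysis run.

Three independent estimators of the extent of conversion:

* base addition -- cumulative NaOH, assuming 2 mol NaOH titrates 1 mol TPA
  (the diacid is essentially fully deprotonated at pH 8);
* products -- TPA equivalents (TPA + MHET + BHET) quantified by UPLC
  or taken from the simulator's ground truth;
* mass loss -- initial minus residual film mass.

Plus pH-profile statistics (rolling mean, fraction of readings inside the
tolerance band) and two scale-planning utilities (enzyme demand across
reactor scales, and how many probe modules a current budget supports).
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConversionResult",
    "ToleranceStats",
    "ModuleBudget",
    "conversion_from_base",
    "conversion_from_products",
    "conversion_from_mass",
    "mhet_fraction",
    "rolling_mean",
    "fraction_in_tolerance",
    "enzyme_reduction_factor",
    "parallel_module_budget",
    "read_products",
    "PRODUCT_COLUMNS",
]

#: tolerated overshoot above 1.0 before an extent is considered suspect
EXTENT_NOISE_ALLOWANCE = 0.05

PRODUCT_COLUMNS = ("time_h", "conc_TPA_mM", "conc_MHET_mM", "conc_BHET_mM")


@dataclass(frozen=True)
class ConversionResult:
    """An extent-of-conversion estimate with its provenance.

    ``flagged`` is set when the estimate exceeds 1 (physically impossible;
    tolerated up to +5% as measurement noise but always flagged).
    """

    method: str  # base_addition | products | mass_loss
    extent: float
    inputs_digest: str = ""

    @property
    def flagged(self) -> bool:
        return self.extent > 1.0 or self.extent < 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.extent


@dataclass(frozen=True)
class ToleranceStats:
    """Fraction of logged readings inside ``target +- tolerance``."""

    fraction_in_tolerance: float
    n_points: int
    target: float
    tolerance: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction_in_tolerance


ModuleBudget = namedtuple("ModuleBudget", ["simultaneous", "total_staggered"])


def conversion_from_base(
    n_naoh: float, initial_pet_mass: float, repeat_unit_mass: float = 192.17
) -> ConversionResult:
    """Extent of conversion from cumulative NaOH, 2 mol base per mol TPA."""
    if n_naoh < 0.0 or repeat_unit_mass <= 0.0:
        raise ValueError("inputs must be >= 0 with repeat_unit_mass > 0")
    if not (initial_pet_mass > 0.0):
        raise ValueError("initial_pet_mass must be > 0")
    extent = (n_naoh / 2.0) * repeat_unit_mass / initial_pet_mass
    return ConversionResult(
        "base_addition",
        extent,
        f"n_naoh={n_naoh:.6g} mol, m0={initial_pet_mass:.6g} g",
    )


def conversion_from_products(
    conc_TPA: float,
    conc_MHET: float,
    conc_BHET: float,
    volume: float,
    initial_pet_mass: float,
    repeat_unit_mass: float = 192.17,
) -> ConversionResult:
    """Extent of conversion from quantified TPA equivalents (mol/L x L)."""
    if min(conc_TPA, conc_MHET, conc_BHET) < 0.0 or volume < 0.0:
        raise ValueError("concentrations and volume must be >= 0")
    if not (initial_pet_mass > 0.0):
        raise ValueError("initial_pet_mass must be > 0")
    n_eq = (conc_TPA + conc_MHET + conc_BHET) * volume
    extent = n_eq * repeat_unit_mass / initial_pet_mass
    return ConversionResult(
        "products",
        extent,
        f"n_eq={n_eq:.6g} mol, V={volume:.6g} L, m0={initial_pet_mass:.6g} g",
    )


def conversion_from_mass(initial_mass: float, final_mass: float) -> ConversionResult:
    """Extent of conversion from residual film mass."""
    if not (initial_mass > 0.0):
        raise ValueError("initial_mass must be > 0")
    if final_mass < 0.0:
        raise ValueError("final_mass must be >= 0")
    extent = (initial_mass - final_mass) / initial_mass
    return ConversionResult(
        "mass_loss",
        extent,
        f"m0={initial_mass:.6g} g, mf={final_mass:.6g} g",
    )


def mhet_fraction(conc_TPA: float, conc_MHET: float, conc_BHET: float) -> float:
    """Molar fraction of MHET in the total aromatic product sum."""
    if min(conc_TPA, conc_MHET, conc_BHET) < 0.0:
        raise ValueError("concentrations must be >= 0")
    total = conc_TPA + conc_MHET + conc_BHET
    if not (total > 0.0):
        raise ValueError("total aromatic product sum must be > 0")
    return conc_MHET / total


def rolling_mean(series, window: int = 50, center: bool = True) -> np.ndarray:
    """Rolling average pH with shrinking windows at the edges.

    The default is a centered window of 50 points; ``center=False`` gives a
    trailing window instead.  Output has the same length as the input.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    n = x.size
    if n == 0:
        return np.empty(0)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    if center:
        lo = np.maximum(0, idx - (window - 1) // 2)
        hi = np.minimum(n, idx + window // 2 + 1)
    else:
        lo = np.maximum(0, idx - window + 1)
        hi = idx + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def fraction_in_tolerance(
    series, target: float, tolerance: float
) -> ToleranceStats:
    """Fraction of readings with ``|x - target| <= tolerance`` (closed band).

    Readings are equispaced in the log, so the per-point fraction equals
    the fraction of reaction time spent inside the band.
    """
    if not (tolerance > 0.0):
        raise ValueError("tolerance must be > 0")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    # widen by a few ulps so boundary readings survive float round-off
    eps = 1e-9 * max(1.0, abs(target))
    inside = np.abs(x - target) <= tolerance + eps
    return ToleranceStats(
        fraction_in_tolerance=float(np.mean(inside)),
        n_points=int(x.size),
        target=float(target),
        tolerance=float(tolerance),
    )


def enzyme_reduction_factor(
    mass_large: float,
    loading_large: float,
    mass_small: float,
    loading_small: float,
) -> float:
    """Fold reduction in purified enzyme demand between two reactor scales.

    ``(mass_large x loading_large) / (mass_small x loading_small)`` with PET
    mass in g and loading in mg enzyme / g PET.
    """
    if min(mass_large, loading_large, mass_small, loading_small) <= 0.0:
        raise ValueError("all inputs must be > 0")
    return (mass_large * loading_large) / (mass_small * loading_small)


def parallel_module_budget(
    supply_mA: float, active_mA: float, sleep_mA: float
) -> ModuleBudget:
    """How many probe modules a current budget supports.

    ``simultaneous`` modules can read at once (``floor(supply/active)``);
    ``total_staggered`` is the largest module count n such that
    ``k*active + (n-k)*sleep <= supply`` with ``k = min(simultaneous, n)``
    concurrent readers and the rest asleep.
    """
    if min(supply_mA, active_mA, sleep_mA) <= 0.0:
        raise ValueError("all currents must be > 0")
    if active_mA < sleep_mA:
        raise ValueError("active current must be >= sleep current")
    simultaneous = int(math.floor(supply_mA / active_mA))
    if simultaneous == 0:
        total = int(math.floor(supply_mA / sleep_mA))
    else:
        total = int(
            math.floor(
                simultaneous + (supply_mA - simultaneous * active_mA) / sleep_mA
            )
        )
    return ModuleBudget(simultaneous=simultaneous, total_staggered=total)


def read_products(path) -> pd.DataFrame:
    """Read a product-concentration table (CSV).

    Required columns: ``time_h, conc_TPA_mM, conc_MHET_mM, conc_BHET_mM``.
    """
    df = pd.read_csv(path, comment="#")
    for col in PRODUCT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"products file is missing column {col!r}")
    return df
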