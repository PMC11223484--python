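"""Acid-base speciation and pH of the reaction medium.

The reaction medium is modelled as a dilute aqueous solution of weak
polyprotic acids (phosphate buffer, terephthalic acid, MHET) together with
strong electrolyte contributed by NaOH dosing.  The pH is the root of the
charge-balance residual

    f(pH) = [Na+] - [strong acid anions] + [H+] - [OH-]
            + sum_i C_i * <z_i>(pH)

where ``<z_i>`` is the mole-fraction-weighted (negative) charge of species
``i`` under standard stepwise dissociation.  ``f`` is strictly decreasing in
pH for fixed totals, so the root is unique and safeguarded bracketing
(Brent's method) converges unconditionally.

Concentrations are treated as activities (ideal-dilute limit) and the
default equilibrium constants are 25 degC literature values; both are
configurable.  See ``docs/methods.md`` for the rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "ProticSpecies",
    "SolutionComposition",
    "charge_balance_residual",
    "solve_ph",
    "sodium_for_target_ph",
    "additional_sodium_for_ph",
    "PHOSPHATE_PKAS",
    "TPA_PKAS",
    "MHET_PKA",
    "DEFAULT_PKW",
]

# Ideal-dilute 25 degC defaults (all overridable through configuration).
PHOSPHATE_PKAS = (2.15, 7.21, 12.33)
TPA_PKAS = (3.51, 4.46)
MHET_PKA = (3.2,)
DEFAULT_PKW = 13.997


@dataclass(frozen=True)
class ProticSpecies:
    """A dissolved acid with one or more dissociable protons.

    Parameters
    ----------
    name : str
        Identifier used to address the species inside a composition
        (e.g. ``"phosphate"``, ``"TPA"``, ``"MHET"``).
    pka_list : tuple of float
        Successive acid dissociation constants as -log10(Ka), strictly
        increasing.  A diacid such as terephthalic acid has two entries.
    charge_fully_protonated : int
        Elementary charge of the fully protonated form (0 for H3PO4,
        0 for H2TPA).
    total_concentration : float
        Total analytical concentration of all protonation states, mol/L.
    """

    name: str
    pka_list: tuple[float, ...]
    charge_fully_protonated: int = 0
    total_concentration: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pka_list", tuple(float(p) for p in self.pka_list))
        if len(self.pka_list) == 0:
            raise ValueError(f"{self.name}: pka_list must be non-empty")
        if any(b <= a for a, b in zip(self.pka_list, self.pka_list[1:])):
            raise ValueError(f"{self.name}: pka_list must be strictly increasing")
        if not (self.total_concentration >= 0.0):
            raise ValueError(f"{self.name}: total_concentration must be >= 0")

    def mean_charge(self, h: float) -> float:
        """Average charge per formula unit at proton activity ``h``.

        Standard stepwise dissociation: the relative abundance of the form
        that has lost ``j`` protons is ``prod_{i<=j} Ka_i / h^j``.
        """
        w = 1.0
        weights = [1.0]
        for pka in self.pka_list:
            w *= 10.0 ** (-pka) / h
            weights.append(w)
        denom = math.fsum(weights)
        z0 = self.charge_fully_protonated
        num = math.fsum(wj * (z0 - j) for j, wj in enumerate(weights))
        return num / denom


@dataclass(frozen=True)
class SolutionComposition:
    """Total composition of the aqueous phase; the state whose pH is solved.

    ``sodium_total`` carries the strong-base cation (Na+ from NaOH dosing
    and from setting the buffer to its starting pH); ``strong_acid_total``
    carries a fully dissociated counter-anion for acid dosing.  Volume is in
    litres; temperature is carried as metadata (equilibrium constants are
    configured, not recomputed from it).
    """

    species: tuple[ProticSpecies, ...] = ()
    sodium_total: float = 0.0
    strong_acid_total: float = 0.0
    volume: float = 1.0
    temperature: float = 25.0
    pKw: float = DEFAULT_PKW

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not (self.volume > 0.0):
            raise ValueError("volume must be > 0")
        if not (self.sodium_total >= 0.0):
            raise ValueError("sodium_total must be >= 0")
        if not (self.strong_acid_total >= 0.0):
            raise ValueError("strong_acid_total must be >= 0")
        if not (self.pKw > 0.0):
            raise ValueError("pKw must be > 0")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    def get_species(self, name: str) -> ProticSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"no species named {name!r}")

    def with_species_conc(self, name: str, conc: float) -> "SolutionComposition":
        """Return a copy with the named species' total set to ``conc`` mol/L."""
        found = False
        out = []
        for sp in self.species:
            if sp.name == name:
                out.append(replace(sp, total_concentration=conc))
                found = True
            else:
                out.append(sp)
        if not found:
            raise KeyError(f"no species named {name!r}")
        return replace(self, species=tuple(out))


def charge_balance_residual(ph: float, solution: SolutionComposition) -> float:
    """Net charge concentration (mol/L) of the solution evaluated at ``ph``.

    Positive means the composition is too alkaline-cation-rich for that pH
    (the true pH lies higher); the function is continuous and strictly
    decreasing in pH for fixed totals.
    """
    if not (isinstance(ph, (int, float)) and math.isfinite(ph)):
        raise ValueError("pH must be a finite number")
    if not (0.0 < ph < solution.pKw + 2.0):
        raise ValueError(f"pH {ph} outside the supported range (0, pKw + 2)")
    h = 10.0 ** (-ph)
    oh = 10.0 ** (ph - solution.pKw)
    res = solution.sodium_total - solution.strong_acid_total + h - oh
    for sp in solution.species:
        if sp.total_concentration > 0.0:
            res += sp.total_concentration * sp.mean_charge(h)
    return res


def solve_ph(solution: SolutionComposition, xtol: float = 1e-10) -> float:
    """pH of the composition: the unique root of the charge balance.

    Raises
    ------
    ValueError
        If the residual does not change sign on (0, pKw), i.e. the
        composition is not consistent with a dilute aqueous solution
        (for example more than ~1 M of excess strong base or acid).
    """
    lo, hi = 1e-6, solution.pKw
    f_lo = charge_balance_residual(lo, solution)
    f_hi = charge_balance_residual(hi, solution)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo < 0.0 or f_hi > 0.0:
        raise ValueError(
            "charge balance has no root in (0, pKw); "
            "composition inconsistent with a dilute aqueous solution"
        )
    return float(
        brentq(charge_balance_residual, lo, hi, args=(solution,), xtol=xtol)
    )


def sodium_for_target_ph(
    solution_without_na: SolutionComposition, target_ph: float
) -> float:
    """Sodium concentration (mol/L) that brings the composition to ``target_ph``.

    Any sodium already present in the input is ignored: the answer is the
    total required.  By electroneutrality this is simply the negated
    charge-balance residual of the sodium-free composition evaluated at the
    target pH.
    """
    if not (0.0 < target_ph < solution_without_na.pKw):
        raise ValueError("target pH must lie in (0, pKw)")
    base = replace(solution_without_na, sodium_total=0.0)
    need = -charge_balance_residual(target_ph, base)
    if need < -1e-12:
        raise ValueError(
            f"target pH {target_ph} is below the sodium-free pH of this "
            "composition; negative sodium would be required"
        )
    return max(need, 0.0)


def additional_sodium_for_ph(
    solution: SolutionComposition, target_ph: float
) -> float:
    """Extra strong base (mol/L, may be negative) to move ``solution`` to ``target_ph``.

    Negative values mean the solution is already above the target and
    strong acid would be required instead.  Used for exact post-hoc
    back-titration when closing the titrant/product stoichiometry.
    """
    if not (0.0 < target_ph < solution.pKw):
        raise ValueError("target pH must lie in (0, pKw)")
    return -charge_balance_residual(target_ph, solution)
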