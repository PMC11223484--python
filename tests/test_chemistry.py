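"""Speciation and charge-balance pH solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phstat.chemistry import (
    PHOSPHATE_PKAS,
    TPA_PKAS,
    ProticSpecies,
    SolutionComposition,
    additional_sodium_for_ph,
    charge_balance_residual,
    sodium_for_target_ph,
    solve_ph,
)

from conftest import buffer_at_ph, phosphate


def random_composition(rng: np.random.Generator) -> SolutionComposition:
    species = []
    for i in range(rng.integers(0, 4)):
        n_pka = int(rng.integers(1, 4))
        pkas = np.sort(rng.uniform(2.0, 12.0, n_pka))
        while np.any(np.diff(pkas) < 0.1):  # keep strictly increasing
            pkas = np.sort(rng.uniform(2.0, 12.0, n_pka))
        species.append(
            ProticSpecies(f"s{i}", tuple(pkas), 0, float(rng.uniform(0.0, 0.2)))
        )
    return SolutionComposition(
        species=tuple(species),
        sodium_total=float(rng.uniform(0.0, 0.3)),
        volume=float(rng.uniform(0.005, 0.5)),
    )


class TestProticSpecies:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ProticSpecies("x", ())
        with pytest.raises(ValueError):
            ProticSpecies("x", (4.0, 3.0))
        with pytest.raises(ValueError):
            ProticSpecies("x", (4.0,), total_concentration=-1e-3)

    def test_diacid_fully_deprotonated_at_high_ph(self):
        tpa = ProticSpecies("TPA", TPA_PKAS, 0, 0.01)
        assert tpa.mean_charge(1e-12) == pytest.approx(-2.0, abs=1e-6)
        # at pH 8 the residual protonation is the 10**(pKa2-8) tail
        assert tpa.mean_charge(1e-8) == pytest.approx(
            -2.0 + 10 ** (TPA_PKAS[1] - 8.0), rel=1e-2
        )


class TestChargeBalanceResidual:
    def test_pure_water_neutral_at_7(self):
        water = SolutionComposition(pKw=14.0)
        assert charge_balance_residual(7.0, water) == pytest.approx(0.0, abs=1e-12)

    def test_strong_base_limit(self):
        naoh = SolutionComposition(sodium_total=1e-3, pKw=14.0)
        assert charge_balance_residual(11.0, naoh) == pytest.approx(0.0, abs=1e-5)

    def test_phosphate_equivalence_at_pka2(self):
        # 100 mM phosphate brought to pH = pKa2 needs ~150 mM Na (equimolar
        # mono-/dibasic forms carry an average charge of -1.5)
        sol = phosphate(0.1, sodium=0.15)
        assert abs(charge_balance_residual(PHOSPHATE_PKAS[1], sol)) < 1e-4

    def test_rejects_nonfinite_and_out_of_range(self):
        water = SolutionComposition()
        with pytest.raises(ValueError):
            charge_balance_residual(float("nan"), water)
        with pytest.raises(ValueError):
            charge_balance_residual(-1.0, water)

    def test_strictly_decreasing_in_ph(self):
        rng = np.random.default_rng(42)
        grid = np.linspace(1.0, 13.0, 200)
        for _ in range(20):
            sol = random_composition(rng)
            vals = [charge_balance_residual(p, sol) for p in grid]
            assert all(b < a for a, b in zip(vals, vals[1:]))


class TestSolvePh:
    def test_pure_water(self):
        assert solve_ph(SolutionComposition(pKw=14.0)) == pytest.approx(7.0, abs=1e-8)

    def test_dilute_naoh(self):
        sol = SolutionComposition(sodium_total=1e-3, pKw=14.0)
        assert solve_ph(sol) == pytest.approx(11.0, abs=0.01)

    def test_phosphate_buffer_at_ph8(self):
        # Henderson-Hasselbalch at pKa2 = 7.21: Na ~ 0.186 M gives pH 8
        sol = phosphate(0.1, sodium=0.186)
        assert solve_ph(sol) == pytest.approx(8.00, abs=0.02)

    def test_inconsistent_composition_raises(self):
        with pytest.raises(ValueError, match="no root"):
            solve_ph(SolutionComposition(sodium_total=2.0))

    def test_matches_grid_scan_on_random_compositions(self):
        # independent oracle: dense sign scan of the residual
        rng = np.random.default_rng(7)
        grid = np.linspace(1.0, 13.5, 125001)  # 1e-4 spacing
        for _ in range(15):
            sol = random_composition(rng)
            vals = np.array([charge_balance_residual(p, sol) for p in grid[::500]])
            # refine around the coarse sign change
            k = int(np.searchsorted(-vals, 0.0))
            lo = grid[::500][max(k - 1, 0)]
            hi = grid[::500][min(k, len(vals) - 1)]
            fine = np.linspace(lo, hi, 2001)
            fvals = np.array([charge_balance_residual(p, sol) for p in fine])
            root_scan = fine[int(np.searchsorted(-fvals, 0.0))]
            assert abs(solve_ph(sol) - root_scan) < 1e-3

    def test_adding_strong_base_never_decreases_ph(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sol = random_composition(rng)
            ph0 = solve_ph(sol)
            more = SolutionComposition(
                species=sol.species,
                sodium_total=sol.sodium_total + float(rng.uniform(0.0, 0.1)),
                volume=sol.volume,
            )
            assert solve_ph(more) >= ph0 - 1e-9

    def test_ph_depends_on_concentrations_not_volume(self):
        # scaling all amounts and the volume together leaves totals (mol/L)
        # and hence the pH unchanged
        sol = buffer_at_ph(8.0)
        import dataclasses

        scaled = dataclasses.replace(sol, volume=sol.volume * 7.0)
        assert solve_ph(scaled) == pytest.approx(solve_ph(sol), abs=1e-12)


class TestSodiumForTargetPh:
    def test_pure_water_needs_none(self):
        water = SolutionComposition(pKw=14.0)
        assert sodium_for_target_ph(water, 7.0) == pytest.approx(0.0, abs=1e-9)

    def test_phosphate_to_ph8(self):
        sol = phosphate(0.1)
        na = sodium_for_target_ph(sol, 8.0)
        assert na == pytest.approx(0.186, abs=1e-3)
        # round trip
        assert solve_ph(phosphate(0.1, sodium=na)) == pytest.approx(8.0, abs=1e-6)

    def test_tpa_needs_two_equivalents_at_ph8(self):
        tpa = SolutionComposition(
            species=(ProticSpecies("TPA", TPA_PKAS, 0, 0.010),)
        )
        # both carboxyls essentially fully deprotonated at pH 8
        assert sodium_for_target_ph(tpa, 8.0) == pytest.approx(0.0200, abs=1e-4)

    def test_target_below_acid_only_ph_rejected(self):
        with pytest.raises(ValueError, match="negative sodium"):
            sodium_for_target_ph(phosphate(0.1), 1.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    conc=st.floats(0.01, 0.2),
    target=st.floats(6.0, 9.0),
    extra=st.floats(1e-4, 0.05),
)
def test_additional_sodium_moves_solution_to_target(conc, target, extra):
    """additional_sodium_for_ph is the exact one-shot titration amount."""
    sol = buffer_at_ph(target, conc)
    import dataclasses

    perturbed = dataclasses.replace(sol, sodium_total=max(sol.sodium_total - extra, 0.0))
    delta = additional_sodium_for_ph(perturbed, target)
    restored = dataclasses.replace(
        perturbed, sodium_total=perturbed.sodium_total + delta
    )
    assert solve_ph(restored) == pytest.approx(target, abs=1e-6)
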