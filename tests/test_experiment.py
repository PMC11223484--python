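"""Closed-loop scheduler and log file round trips."""

import dataclasses
import math

import pytest

from phstat import experiment
from phstat.chemistry import (
    MHET_PKA,
    TPA_PKAS,
    ProticSpecies,
    sodium_for_target_ph,
)
from phstat.controller import ControlSettings
from phstat.experiment import Schedule, read_log, run, write_log
from phstat.kinetics import EnzymePool, FilmSubstrate, ProductPool
from phstat.plant import ProbeModel, PumpModel, ReactorState

from conftest import phosphate


def small_state(initial_ph=8.0, enzyme=None) -> ReactorState:
    sol = phosphate(0.1)
    sol = dataclasses.replace(
        sol,
        species=sol.species
        + (
            ProticSpecies("TPA", TPA_PKAS, 0, 0.0),
            ProticSpecies("MHET", MHET_PKA, 0, 0.0),
        ),
        volume=0.012,
    )
    sol = dataclasses.replace(sol, sodium_total=sodium_for_target_ph(sol, initial_ph))
    return ReactorState(
        solution=sol,
        substrate=FilmSubstrate(),
        products=ProductPool(),
        enzyme=enzyme or EnzymePool(),
    )


def quiet_settings(**kw) -> ControlSettings:
    defaults = dict(target_ph=8.0, tolerance=0.1, cycle_time=90.0)
    defaults.update(kw)
    return ControlSettings(**defaults)


class TestRun:
    def test_record_count(self):
        state = small_state(enzyme=EnzymePool(loading=0.0))
        schedule = Schedule(duration=1.0, measure_interval=30.0, kinetics_dt=10.0)
        result = run(state, ProbeModel(), PumpModel(), quiet_settings(), schedule, 1)
        assert len(result.records) == math.floor(3600 / 30) + 1

    def test_zero_enzyme_run_stays_at_initial_ph(self):
        state = small_state(enzyme=EnzymePool(loading=0.0))
        schedule = Schedule(duration=1.0)
        result = run(state, ProbeModel(), PumpModel(), quiet_settings(), schedule, 1)
        assert result.controller_state.dose_count == 0
        for r in result.records:
            assert abs(r.ph_reading - 8.0) < 0.1  # within probe noise

    def test_seeded_run_is_reproducible(self):
        state = small_state()
        schedule = Schedule(duration=2.0)
        a = run(state, ProbeModel(), PumpModel(), quiet_settings(), schedule, 42)
        b = run(state, ProbeModel(), PumpModel(), quiet_settings(), schedule, 42)
        assert a.records == b.records

    def test_budget_of_one_dose_then_halt(self):
        # start below the band with a titrant too weak to correct the pH:
        # exactly one dose fits the budget, then the controller latches
        state = small_state(initial_ph=7.5, enzyme=EnzymePool(loading=0.0))
        pump = PumpModel(nominal_dose=40.0, dose_sd=0.0, titrant_concentration=1e-9)
        settings = quiet_settings(max_added_volume=0.04, titrant_concentration=1e-9)
        schedule = Schedule(duration=0.25)
        result = run(state, ProbeModel(noise_sd=0.0), pump, settings, schedule, 0)
        actions = [r.action for r in result.records]
        assert result.controller_state.dose_count == 1
        assert actions.count("dose_base") == 1
        assert actions.count("halt") == 1
        assert actions.index("dose_base") < actions.index("halt")
        assert result.controller_state.halted

    def test_controller_books_match_plant_without_pump_noise(self):
        state = small_state()
        pump = PumpModel(nominal_dose=40.0, dose_sd=0.0)
        result = run(state, ProbeModel(), pump, quiet_settings(), Schedule(duration=6.0), 3)
        assert result.final_state.volume_added == pytest.approx(
            result.controller_state.cumulative_volume, abs=1e-12
        )

    def test_final_record_book_keeping_identity(self, chibio_run):
        _, result = chibio_run
        last = result.records[-1]
        assert last.dose_count * 40.0 == pytest.approx(
            last.cumulative_volume_mL * 1000.0
        )

    def test_sample_events_reduce_volume(self):
        state = small_state(enzyme=EnzymePool(loading=0.0))
        schedule = Schedule(duration=1.0, sample_events=((0.5, 0.1),))
        result = run(state, ProbeModel(), PumpModel(), quiet_settings(), schedule, 1)
        assert result.final_state.solution.volume == pytest.approx(0.012 - 1e-4)

    def test_mismatched_pump_rejected(self):
        state = small_state()
        acid_pump = PumpModel(titrant_sign="acid")
        with pytest.raises(ValueError, match="base pump"):
            run(state, ProbeModel(), acid_pump, quiet_settings(), Schedule(duration=0.1), 0)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            Schedule(duration=0.0)
        with pytest.raises(ValueError):
            Schedule(duration=1.0, measure_interval=30.0, kinetics_dt=31.0)


class TestLogIO:
    def test_empty_records_gives_header_only(self, tmp_path):
        path = tmp_path / "log.csv"
        write_log([], path)
        assert path.read_text() == experiment.LOG_HEADER + "\n"
        records, _ = read_log(path)
        assert records == []

    def test_round_trip_is_exact(self, tmp_path, chibio_run):
        _, result = chibio_run
        path = tmp_path / "log.csv"
        write_log(result.records, path, {"seed": 11, "scenario": "small"})
        records, metadata = read_log(path)
        assert metadata["seed"] == "11"
        assert list(records) == list(result.records)

    def test_hardware_log_without_ph_true(self, tmp_path):
        path = tmp_path / "hw.csv"
        path.write_text(
            "time_s,ph_reading,dose_count,cumulative_volume_mL,action\n"
            "0.0,8.0,0,0.0,none\n"
            "30.0,7.89,1,0.04,dose_base\n"
        )
        records, _ = read_log(path)
        assert [r.ph_true for r in records] == [None, None]
        assert records[1].dose_count == 1

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            experiment.LOG_HEADER + "\n"
            "0.0,8.0,8.0,0,0.0,none\n"
            "30.0,oops,8.0,0,0.0,none\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_log(path)

    def test_time_reversal_rejected(self, tmp_path):
        path = tmp_path / "rev.csv"
        path.write_text(
            experiment.LOG_HEADER + "\n"
            "30.0,8.0,8.0,0,0.0,none\n"
            "0.0,8.0,8.0,0,0.0,none\n"
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            read_log(path)
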