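"""Event-loop scheduler and the run-log file format.

The simulation clock is discrete-event: kinetics sub-steps at
``kinetics_dt``, a probe reading every ``measure_interval`` seconds, and a
control decision whenever a full ``cycle_time`` has elapsed since the last
one.  A dose (deliver + record) is atomic.  The run log is a CSV with the
exact header::

    time_s,ph_reading,ph_true,dose_count,cumulative_volume_mL,action

preceded by optional ``# key: value`` comment lines carrying run metadata
(seed, config digest, titrant concentration, initial PET mass) so the log
is self-describing for downstream analysis.  Hardware logs lack the
``ph_true`` column; the reader tolerates its absence.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .chemistry import solve_ph
from .controller import (
    Action,
    ControllerState,
    ControlSettings,
    decide,
    halt as _halt,
    mark_cycle,
    record_dose,
)
from .plant import (
    ProbeModel,
    PumpModel,
    ReactorState,
    advance,
    deliver_dose,
    withdraw_sample,
)

__all__ = [
    "Schedule",
    "LogRecord",
    "RunResult",
    "run",
    "write_log",
    "read_log",
    "LOG_HEADER",
]

LOG_HEADER = "time_s,ph_reading,ph_true,dose_count,cumulative_volume_mL,action"


@dataclass(frozen=True)
class Schedule:
    """Timing of the experiment.

    duration in hours; intervals in seconds.  ``ui_report_interval`` is
    retained for fidelity with the reactor UI but drives no separate
    output (reporting collapses onto the log).  ``sample_events`` is a
    sequence of ``(time_h, volume_mL)`` liquid withdrawals.
    """

    duration: float = 72.0
    measure_interval: float = 30.0
    ui_report_interval: float = 30.0
    kinetics_dt: float = 10.0
    sample_events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (self.duration > 0.0):
            raise ValueError("duration must be > 0")
        if not (0.0 < self.kinetics_dt <= self.measure_interval):
            raise ValueError("need 0 < kinetics_dt <= measure_interval")
        object.__setattr__(
            self,
            "sample_events",
            tuple(sorted((float(t), float(v)) for t, v in self.sample_events)),
        )
        for t, v in self.sample_events:
            if t < 0.0 or v <= 0.0:
                raise ValueError("sample events need time >= 0 and volume > 0")


@dataclass(frozen=True)
class LogRecord:
    time_s: float
    ph_reading: float
    ph_true: float | None
    dose_count: int
    cumulative_volume_mL: float
    action: str


@dataclass(frozen=True)
class RunResult:
    """Log plus the final ground-truth plant and controller states."""

    records: tuple[LogRecord, ...]
    final_state: ReactorState
    controller_state: ControllerState

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _pump_table(pump) -> dict[Action, PumpModel]:
    if isinstance(pump, PumpModel):
        pumps = [pump]
    else:
        pumps = list(pump)
    table: dict[Action, PumpModel] = {}
    for p in pumps:
        key = Action.DOSE_BASE if p.titrant_sign == "base" else Action.DOSE_ACID
        if key in table:
            raise ValueError(f"duplicate pump for {key.value}")
        table[key] = p
    return table


def run(
    plant_initial: ReactorState,
    probe: ProbeModel,
    pump,
    settings: ControlSettings,
    schedule: Schedule,
    rng_seed=None,
) -> RunResult:
    """Run the closed loop and return the log with the final states.

    ``pump`` is a single :class:`PumpModel` or a sequence of them (one per
    titrant sign, for two-sided control).  Deterministic for a fixed
    ``rng_seed``.
    """
    pumps = _pump_table(pump)
    from .controller import Mode

    if settings.mode in (Mode.BASE_ONLY, Mode.TWO_SIDED) and Action.DOSE_BASE not in pumps:
        raise ValueError("mode permits base dosing but no base pump was given")
    if settings.mode in (Mode.ACID_ONLY, Mode.TWO_SIDED) and Action.DOSE_ACID not in pumps:
        raise ValueError("mode permits acid dosing but no acid pump was given")

    rng = np.random.default_rng(rng_seed)
    state = plant_initial
    cstate = ControllerState()
    n_meas = int(math.floor(schedule.duration * 3600.0 / schedule.measure_interval + 1e-9))
    nsub = max(1, math.ceil(schedule.measure_interval / schedule.kinetics_dt - 1e-9))
    sub_dt_h = schedule.measure_interval / nsub / 3600.0
    events = list(schedule.sample_events)
    ei = 0

    records: list[LogRecord] = []
    for i in range(n_meas + 1):
        now = i * schedule.measure_interval
        if i > 0:
            for _ in range(nsub):
                state = advance(state, sub_dt_h)
            while ei < len(events) and events[ei][0] * 3600.0 <= now + 1e-9:
                state = withdraw_sample(state, events[ei][1])
                ei += 1
        true_ph = solve_ph(state.solution)
        reading = probe.observe(true_ph, rng)
        action = decide(reading, now, settings, cstate)
        if action in (Action.DOSE_BASE, Action.DOSE_ACID):
            state, _ = deliver_dose(state, pumps[action], rng)
            cstate = record_dose(cstate, settings, now)
        elif action is Action.HALT:
            cstate = _halt(cstate, now)
        elif now - cstate.last_decision_time >= settings.cycle_time:
            cstate = mark_cycle(cstate, now)
        records.append(
            LogRecord(
                time_s=float(now),
                ph_reading=float(reading),
                ph_true=float(true_ph),
                dose_count=cstate.dose_count,
                cumulative_volume_mL=cstate.cumulative_volume,
                action=action.value,
            )
        )
    return RunResult(tuple(records), state, cstate)


def write_log(records, path, metadata: dict | None = None) -> None:
    """Write records to ``path`` as the canonical log CSV.

    Floats are written with ``repr`` so the read/write round trip is exact.
    ``metadata`` entries become leading ``# key: value`` comment lines.
    """
    with open(path, "w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write(LOG_HEADER + "\n")
        for r in records:
            true = "" if r.ph_true is None else repr(float(r.ph_true))
            fh.write(
                f"{float(r.time_s)!r},{float(r.ph_reading)!r},{true},"
                f"{int(r.dose_count)},{float(r.cumulative_volume_mL)!r},{r.action}\n"
            )


def read_log(path) -> tuple[list[LogRecord], dict]:
    """Read a log CSV; returns (records, metadata).

    Tolerates a missing ``ph_true`` column (hardware logs); malformed rows
    raise ``ValueError`` naming the offending line number.
    """
    metadata: dict[str, str] = {}
    records: list[LogRecord] = []
    header: list[str] | None = None
    has_true = True
    expected = LOG_HEADER.split(",")
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            row = next(csv.reader([line]))
            if header is None:
                header = [c.strip() for c in row]
                if header == expected:
                    has_true = True
                elif header == [c for c in expected if c != "ph_true"]:
                    has_true = False
                else:
                    raise ValueError(
                        f"line {lineno}: unrecognized log header {header!r}"
                    )
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                fields = dict(zip(header, row))
                ph_true: float | None = None
                if has_true and fields["ph_true"] != "":
                    ph_true = float(fields["ph_true"])
                rec = LogRecord(
                    time_s=float(fields["time_s"]),
                    ph_reading=float(fields["ph_reading"]),
                    ph_true=ph_true,
                    dose_count=int(fields["dose_count"]),
                    cumulative_volume_mL=float(fields["cumulative_volume_mL"]),
                    action=fields["action"],
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"line {lineno}: malformed row: {exc}") from exc
            if records:
                if rec.time_s <= records[-1].time_s:
                    raise ValueError(
                        f"line {lineno}: time_s not strictly increasing"
                    )
                if rec.cumulative_volume_mL < records[-1].cumulative_volume_mL:
                    raise ValueError(
                        f"line {lineno}: cumulative_volume_mL decreased"
                    )
            records.append(rec)
    if header is None:
        raise ValueError("log file has no header")
    return records, metadata
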