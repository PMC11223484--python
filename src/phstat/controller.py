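"""pH-stat decision logic: on-off (bang-bang) control with a dead zone.

Every cycle_time seconds the controller compares the latest pH reading to
the band ``target +- tolerance`` (closed interval: boundary readings do not
trigger a dose).  Outside the band it issues exactly one fixed-volume dose
in the correcting direction, if the configured mode permits that direction;
large deviations are corrected over multiple cycles.  A cumulative-volume
budget guards against reactor overflow: a dose that would exceed it is
replaced by a latched halt.

Book-keeping mirrors a hardware pH-stat: the controller counts pump
activations and multiplies by the user-set dose volume.  This can differ
from the plant's ground-truth delivered volume by pump scatter only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

__all__ = [
    "Action",
    "Mode",
    "ControlSettings",
    "ControllerState",
    "decide",
    "record_dose",
    "mark_cycle",
    "halt",
    "moles_titrant",
]

_BUDGET_EPS = 1e-12  # mL; guards float round-off in the budget comparison


class Action(str, Enum):
    NONE = "none"
    DOSE_BASE = "dose_base"
    DOSE_ACID = "dose_acid"
    HALT = "halt"


class Mode(str, Enum):
    BASE_ONLY = "base_only"
    ACID_ONLY = "acid_only"
    TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class ControlSettings:
    """User-facing pH-stat parameters (the reactor UI's input boxes)."""

    target_ph: float = 8.0
    tolerance: float = 0.1  # pH units
    cycle_time: float = 90.0  # s between control decisions
    measure_interval: float = 30.0  # s between pH readings
    mode: Mode = Mode.BASE_ONLY
    set_dose_volume: float = 40.0  # uL per pump activation
    titrant_concentration: float = 1.0  # mol/L
    max_added_volume: float = 15.0  # mL, overflow guard
    pump_line: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if not (self.tolerance > 0.0):
            raise ValueError("tolerance must be > 0")
        if not (self.cycle_time >= self.measure_interval > 0.0):
            raise ValueError("cycle_time must be >= measure_interval > 0")
        if not (self.set_dose_volume > 0.0):
            raise ValueError("set_dose_volume must be > 0")
        if not (self.max_added_volume > 0.0):
            raise ValueError("max_added_volume must be > 0")
        if not (self.titrant_concentration > 0.0):
            raise ValueError("titrant_concentration must be > 0")
        if not math.isfinite(self.target_ph):
            raise ValueError("target_ph must be finite")


@dataclass(frozen=True)
class ControllerState:
    """Controller book-keeping; cumulative_volume == dose_count x dose volume."""

    dose_count: int = 0
    cumulative_volume: float = 0.0  # mL
    last_decision_time: float = 0.0  # s
    halted: bool = False


def decide(
    reading: float,
    now: float,
    settings: ControlSettings,
    cstate: ControllerState,
) -> Action:
    """One control decision for the latest reading at time ``now`` (s)."""
    if not math.isfinite(reading):
        raise ValueError("reading must be finite")
    if now < cstate.last_decision_time:
        raise ValueError("now must be >= last_decision_time")
    if cstate.halted:
        return Action.NONE
    if now - cstate.last_decision_time < settings.cycle_time:
        return Action.NONE
    deviation = reading - settings.target_ph
    if abs(deviation) <= settings.tolerance:
        return Action.NONE
    if deviation < 0.0:
        wanted, permitted = Action.DOSE_BASE, settings.mode in (
            Mode.BASE_ONLY,
            Mode.TWO_SIDED,
        )
    else:
        wanted, permitted = Action.DOSE_ACID, settings.mode in (
            Mode.ACID_ONLY,
            Mode.TWO_SIDED,
        )
    if not permitted:
        return Action.NONE
    next_volume = cstate.cumulative_volume + settings.set_dose_volume / 1000.0
    if next_volume > settings.max_added_volume + _BUDGET_EPS:
        return Action.HALT
    return wanted


def record_dose(
    cstate: ControllerState, settings: ControlSettings, now: float | None = None
) -> ControllerState:
    """Account for one pump activation at time ``now``."""
    if cstate.halted:
        raise RuntimeError("cannot record a dose on a halted controller")
    count = cstate.dose_count + 1
    # Recomputed as a product so count x dose == cumulative holds exactly.
    cumulative = count * settings.set_dose_volume / 1000.0
    return replace(
        cstate,
        dose_count=count,
        cumulative_volume=cumulative,
        last_decision_time=cstate.last_decision_time if now is None else now,
    )


def mark_cycle(cstate: ControllerState, now: float) -> ControllerState:
    """Restart the cycle clock after a no-dose (or halt) decision."""
    return replace(cstate, last_decision_time=now)


def halt(cstate: ControllerState, now: float) -> ControllerState:
    """Latch the controller; it issues no further doses until reset."""
    return replace(cstate, halted=True, last_decision_time=now)


def moles_titrant(cstate: ControllerState, settings: ControlSettings) -> float:
    """Moles of titrant added according to the controller's own book-keeping."""
    return cstate.cumulative_volume / 1000.0 * settings.titrant_concentration
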