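"""Alarm evaluation, prioritization, latching and logging.

The alarm set mirrors the safety monitoring of a pressure-controlled
ventilator: high/low airway pressure, hyper-/hypoventilation, obstruction,
low FiO2, PEEP not met, disconnect/high leakage and technical faults.
High-pressure, FiO2 and technical conditions are evaluated at the control
tick rate (so detection latency is bounded by persistence * control period);
breath-statistics conditions are evaluated once per completed breath.
Alarms are episodic: each episode has exactly one onset and at most one
clear, and an episode may latch (remain visible) after the condition clears
until acknowledged, which is the usual safety-device convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum

import pandas as pd

from .controller import VentSettings
from .lung import SensorFrame
from .metrics import BreathRecord

__all__ = [
    "AlarmType",
    "Priority",
    "AlarmRule",
    "AlarmEvent",
    "AlarmManager",
    "default_rules",
    "evaluate_alarms",
    "highest_priority",
    "alarms_to_frame",
]


class AlarmType(Enum):
    HIGH_PRESSURE = "HIGH_PRESSURE"
    LOW_PRESSURE = "LOW_PRESSURE"
    HYPERVENTILATION = "HYPERVENTILATION"
    HYPOVENTILATION = "HYPOVENTILATION"
    OBSTRUCTION = "OBSTRUCTION"
    LOW_FIO2 = "LOW_FIO2"
    PEEP_NOT_MET = "PEEP_NOT_MET"
    DISCONNECT_LEAK = "DISCONNECT_LEAK"
    TECHNICAL = "TECHNICAL"


# bit positions for the waveform alarm mask channel
ALARM_BIT = {t: i for i, t in enumerate(AlarmType)}


class Priority(IntEnum):
    low = 1
    medium = 2
    high = 3


# which rules are checked every control tick vs once per breath
TICK_RULES = {AlarmType.HIGH_PRESSURE, AlarmType.LOW_FIO2, AlarmType.TECHNICAL}


@dataclass(frozen=True)
class AlarmRule:
    """One alarm condition.

    ``threshold`` has rule-specific units (cmH2O, fraction, breaths/min or a
    dimensionless ratio); ``persistence`` counts control ticks for tick-rate
    rules and completed breaths for breath-rate rules.
    """

    alarm_type: AlarmType
    priority: Priority
    threshold: float
    persistence: int = 1

    def __post_init__(self) -> None:
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class AlarmEvent:
    """One alarm episode; ``clear_time`` is None while the episode is open."""

    alarm_type: AlarmType
    priority: Priority
    onset_time: float
    clear_time: float | None = None
    observed_value: float = float("nan")
    limit_value: float = float("nan")

    @property
    def active(self) -> bool:
        return self.clear_time is None


def default_rules(settings: VentSettings) -> list[AlarmRule]:
    """Default alarm rule set derived from the ventilation settings.

    Thresholds: HIGH_PRESSURE at the HAPA limit (3 ticks); LOW_PRESSURE when
    measured PIP falls 5 cmH2O under target (3 breaths); HYPOVENTILATION when
    measured RR < 0.5x set RR or VTE < 50% of its rolling median (3 breaths);
    HYPERVENTILATION when measured RR > 1.5x set RR (3 breaths); PEEP_NOT_MET
    when measured PEEP is 3 cmH2O under the setting (3 breaths); LOW_FIO2
    when the reading drops 0.05 under the set fraction; DISCONNECT_LEAK when
    inspiratory plateau pressure collapses below 5 cmH2O or the
    inspired/exhaled volume mismatch exceeds 25%; TECHNICAL on non-finite
    sensor data.  All thresholds are configurable by passing a custom list.
    """
    return [
        AlarmRule(AlarmType.HIGH_PRESSURE, Priority.high, settings.hapa_limit, 3),
        AlarmRule(AlarmType.LOW_PRESSURE, Priority.medium, settings.pip_target - 5.0, 3),
        AlarmRule(AlarmType.HYPOVENTILATION, Priority.medium, 0.5, 3),
        AlarmRule(AlarmType.HYPERVENTILATION, Priority.medium, 1.5, 3),
        AlarmRule(AlarmType.PEEP_NOT_MET, Priority.medium, settings.peep_setting - 3.0, 3),
        AlarmRule(AlarmType.LOW_FIO2, Priority.medium, settings.fio2_set - 0.05, 3),
        AlarmRule(AlarmType.OBSTRUCTION, Priority.medium, 0.25, 3),
        AlarmRule(AlarmType.DISCONNECT_LEAK, Priority.high, 0.25, 3),
        AlarmRule(AlarmType.TECHNICAL, Priority.high, 0.0, 1),
    ]


class AlarmManager:
    """Evaluates rules, tracks debounce counters and episode lifecycles."""

    def __init__(
        self,
        rules: list[AlarmRule],
        settings: VentSettings,
        latch_until_ack: bool = False,
    ):
        seen: set[AlarmType] = set()
        for rule in rules:
            if rule.alarm_type in seen:
                raise ValueError(f"duplicate rule for {rule.alarm_type}")
            if not isinstance(rule.alarm_type, AlarmType):
                raise ValueError(f"unknown alarm type {rule.alarm_type!r}")
            seen.add(rule.alarm_type)
        self.rules = {r.alarm_type: r for r in rules}
        self.settings = settings
        self.latch_until_ack = latch_until_ack
        self._counters: dict[AlarmType, int] = {t: 0 for t in self.rules}
        self._open: dict[AlarmType, AlarmEvent] = {}
        self._latched: dict[AlarmType, AlarmEvent] = {}
        self.log: list[AlarmEvent] = []
        self._vte_history: list[float] = []
        self._breath_starts: list[float] = []

    # -- lifecycle -----------------------------------------------------
    def _raise(self, rule: AlarmRule, time: float, observed: float, limit: float) -> None:
        if rule.alarm_type in self._open:
            return
        event = AlarmEvent(rule.alarm_type, rule.priority, time, None, observed, limit)
        self._open[rule.alarm_type] = event
        self.log.append(event)

    def _clear(self, alarm_type: AlarmType, time: float) -> None:
        event = self._open.pop(alarm_type, None)
        if event is not None:
            event.clear_time = time
            if self.latch_until_ack:
                self._latched[alarm_type] = event

    def acknowledge(self) -> None:
        """Dismiss latched (condition-cleared) alarms from the display list."""
        self._latched.clear()

    def _update_condition(
        self, rule: AlarmRule, condition: bool, time: float, observed: float, limit: float
    ) -> None:
        if condition:
            self._counters[rule.alarm_type] += 1
            if self._counters[rule.alarm_type] >= rule.persistence:
                self._raise(rule, time, observed, limit)
        else:
            self._counters[rule.alarm_type] = 0
            self._clear(rule.alarm_type, time)

    # -- evaluation ----------------------------------------------------
    def update_tick(self, frame: SensorFrame) -> None:
        """Per-tick rules: high pressure, low FiO2, technical."""
        t = frame.time
        rule = self.rules.get(AlarmType.TECHNICAL)
        if rule is not None:
            bad = not (
                math.isfinite(frame.pressure_reading)
                and math.isfinite(frame.flow_reading)
                and math.isfinite(frame.time)
            )
            self._update_condition(rule, bad, t, float("nan"), 0.0)
            if bad:
                return  # do not feed non-finite values to the other rules
        rule = self.rules.get(AlarmType.HIGH_PRESSURE)
        if rule is not None:
            self._update_condition(
                rule, frame.pressure_reading > rule.threshold, t,
                frame.pressure_reading, rule.threshold,
            )
        rule = self.rules.get(AlarmType.LOW_FIO2)
        if rule is not None:
            self._update_condition(
                rule, frame.fio2_reading < rule.threshold, t,
                frame.fio2_reading, rule.threshold,
            )

    def update_breath(self, breath: BreathRecord) -> None:
        """Per-breath rules, called once per completed cycle in order."""
        t = breath.start_time
        self._breath_starts.append(t)
        set_rr = self.settings.respiratory_rate

        measured_rr = float("nan")
        if len(self._breath_starts) >= 3:
            recent = self._breath_starts[-4:]
            intervals = [b - a for a, b in zip(recent[:-1], recent[1:])]
            mean_int = sum(intervals) / len(intervals)
            if mean_int > 0:
                measured_rr = 60.0 / mean_int

        rolling = sorted(self._vte_history[-10:])
        vte_median = rolling[len(rolling) // 2] if rolling else float("nan")
        self._vte_history.append(breath.vte)

        rule = self.rules.get(AlarmType.LOW_PRESSURE)
        if rule is not None:
            self._update_condition(
                rule, breath.measured_pip < rule.threshold, t,
                breath.measured_pip, rule.threshold,
            )
        rule = self.rules.get(AlarmType.PEEP_NOT_MET)
        if rule is not None:
            self._update_condition(
                rule, breath.measured_peep < rule.threshold, t,
                breath.measured_peep, rule.threshold,
            )
        rule = self.rules.get(AlarmType.HYPOVENTILATION)
        if rule is not None:
            slow = math.isfinite(measured_rr) and measured_rr < rule.threshold * set_rr
            small = math.isfinite(vte_median) and breath.vte < 0.5 * vte_median
            self._update_condition(
                rule, slow or small, t,
                measured_rr if slow else breath.vte,
                rule.threshold * set_rr if slow else 0.5 * vte_median,
            )
        rule = self.rules.get(AlarmType.HYPERVENTILATION)
        if rule is not None:
            fast = math.isfinite(measured_rr) and measured_rr > rule.threshold * set_rr
            self._update_condition(rule, fast, t, measured_rr, rule.threshold * set_rr)
        rule = self.rules.get(AlarmType.OBSTRUCTION)
        if rule is not None:
            at_target = breath.measured_pip >= self.settings.pip_target - 2.0
            blocked = (
                at_target
                and math.isfinite(vte_median)
                and breath.vte < rule.threshold * vte_median
            )
            self._update_condition(
                rule, blocked, t, breath.vte,
                rule.threshold * (vte_median if math.isfinite(vte_median) else 0.0),
            )
        rule = self.rules.get(AlarmType.DISCONNECT_LEAK)
        if rule is not None:
            no_plateau = breath.measured_pip < 5.0
            ref = max(breath.inspired_volume, breath.vte)
            mismatch = (
                abs(breath.inspired_volume - breath.vte) / ref if ref > 0 else 0.0
            )
            leak = mismatch > rule.threshold
            self._update_condition(
                rule, no_plateau or leak, t,
                breath.measured_pip if no_plateau else mismatch,
                5.0 if no_plateau else rule.threshold,
            )

    # -- queries ---------------------------------------------------------
    def active(self) -> list[AlarmEvent]:
        """Currently-raised episodes plus latched, unacknowledged ones."""
        events = list(self._open.values())
        events.extend(e for t, e in self._latched.items() if t not in self._open)
        return sorted(events, key=lambda e: e.onset_time)

    def active_mask(self) -> int:
        mask = 0
        for event in self._open.values():
            mask |= 1 << ALARM_BIT[event.alarm_type]
        return mask

    def finalize(self, time: float) -> None:
        """Close any still-open episodes at end of run (clear time = end)."""
        for alarm_type in list(self._open):
            self._clear(alarm_type, time)


def evaluate_alarms(
    frame: SensorFrame,
    latest_breaths: list[BreathRecord],
    rules: list[AlarmRule],
    manager: AlarmManager | None = None,
    settings: VentSettings | None = None,
) -> tuple[list[AlarmEvent], AlarmManager]:
    """Functional entry point: feed one frame (and any newly completed
    breaths) through an alarm manager and return the active events.

    Creates the manager on first call; pass the returned manager back in on
    subsequent calls to keep counters and episodes.
    """
    if manager is None:
        if settings is None:
            raise ValueError("settings required to create an alarm manager")
        manager = AlarmManager(rules, settings)
    for breath in latest_breaths:
        manager.update_breath(breath)
    manager.update_tick(frame)
    return manager.active(), manager


def highest_priority(events: list[AlarmEvent]) -> Priority | None:
    """Maximum priority among active events; None when there are none."""
    active = [e for e in events if e.active]
    if not active:
        return None
    return max(e.priority for e in active)


def alarms_to_frame(events: list[AlarmEvent]) -> pd.DataFrame:
    """Alarm log as a table (columns: type, priority, onset_s, clear_s,
    observed, limit)."""
    return pd.DataFrame(
        [
            {
                "type": e.alarm_type.value,
                "priority": e.priority.name,
                "onset_s": e.onset_time,
                "clear_s": float("nan") if e.clear_time is None else e.clear_time,
                "observed": e.observed_value,
                "limit": e.limit_value,
            }
            for e in events
        ],
        columns=["type", "priority", "onset_s", "clear_s", "observed", "limit"],
    ).astype(
        {"type": str, "priority": str, "onset_s": float, "clear_s": float,
         "observed": float, "limit": float}
    )
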