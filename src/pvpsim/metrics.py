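"""Waveform segmentation and per-breath respiratory metrics.

Splits a uniformly sampled waveform into breath cycles on inspiration
onsets and computes the display/derived variables of a pressure-controlled
ventilator: measured PIP (maximum airway pressure during inspiration),
measured PEEP (mean pressure over the final fraction of expiration),
expiratory tidal volume VTE (trapezoidal integral of expiratory flow),
inspired volume (integral of inspiratory flow), rise time (first crossing
of target-PIP-minus-band from inspiration onset) and mean airway pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controller import PHASE_EXPIRE, PHASE_INSPIRE, VentSettings

__all__ = [
    "WaveformRecord",
    "BreathRecord",
    "segment_breaths",
    "breath_metrics",
    "estimate_compliance",
    "aggregate_metrics",
    "breaths_to_frame",
]

# "Reached PIP" band for the rise-time metric: first crossing of
# (pip_target - RISE_BAND) from inspiration onset.  Configurable per call.
RISE_BAND = 1.0
# Measured PEEP = mean pressure over the final fraction of expiration.
PEEP_WINDOW_FRACTION = 0.1

LPM_TO_MLPS = 1000.0 / 60.0  # L/min -> mL/s


@dataclass
class WaveformRecord:
    """Uniformly sampled channels of one simulation run.

    time in s, pressure in cmH2O, flows in L/min, volume in mL above
    residual capacity; phase uses the controller phase codes; alarm_mask is
    a bitmask of active alarm types per sample.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow_in: np.ndarray
    flow_out: np.ndarray
    volume: np.ndarray
    phase: np.ndarray
    valve_drive: np.ndarray
    expiratory_valve_open: np.ndarray
    alarm_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.alarm_mask is None:
            self.alarm_mask = np.zeros(n, dtype=np.uint16)
        channels = (
            self.pressure,
            self.flow_in,
            self.flow_out,
            self.volume,
            self.phase,
            self.valve_drive,
            self.expiratory_valve_open,
            self.alarm_mask,
        )
        if any(len(c) != n for c in channels):
            raise ValueError("all waveform channels must have equal length")
        if n >= 2:
            dts = np.diff(self.time)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("waveform sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) >= 2 else 0.0

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pressure_cmH2O": self.pressure,
                "flow_in_Lpm": self.flow_in,
                "flow_out_Lpm": self.flow_out,
                "volume_mL": self.volume,
                "phase": self.phase,
                "valve_drive": self.valve_drive,
                "exp_valve_open": self.expiratory_valve_open.astype(np.uint8),
                "alarm_mask": self.alarm_mask,
            }
        )


@dataclass
class BreathRecord:
    """Per-cycle derived metrics."""

    cycle_index: int
    start_time: float
    measured_pip: float
    measured_peep: float
    vte: float  # mL
    inspired_volume: float  # mL
    rise_time: float  # s; NaN if target band never reached
    mean_airway_pressure: float
    spontaneous: bool = False

    def __post_init__(self) -> None:
        if self.vte < 0:
            raise ValueError("vte must be >= 0")


METRIC_COLUMNS = [
    "measured_pip",
    "measured_peep",
    "vte",
    "inspired_volume",
    "rise_time",
    "mean_airway_pressure",
]


def segment_breaths(record: WaveformRecord) -> list[tuple[int, int]]:
    """Index ranges [start, end) of complete breath cycles.

    A cycle starts at each EXPIRE->INSPIRE transition of the phase channel
    (plus sample 0 if the record begins mid-inspiration).  The trailing
    incomplete cycle is dropped.
    """
    if len(record) == 0:
        raise ValueError("empty waveform record")
    phase = np.asarray(record.phase)
    onsets = np.flatnonzero(
        (phase[1:] == PHASE_INSPIRE) & (phase[:-1] == PHASE_EXPIRE)
    ) + 1
    if phase[0] == PHASE_INSPIRE:
        onsets = np.concatenate(([0], onsets))
    return [(int(a), int(b)) for a, b in zip(onsets[:-1], onsets[1:])]


def breath_metrics(
    record: WaveformRecord,
    segment: tuple[int, int],
    settings: VentSettings,
    cycle_index: int = 0,
    spontaneous: bool = False,
    rise_band: float = RISE_BAND,
    peep_window_fraction: float = PEEP_WINDOW_FRACTION,
) -> BreathRecord:
    """Compute the derived variables for one complete breath segment."""
    a, b = segment
    if b <= a:
        raise ValueError("segment must be non-empty")
    t = record.time[a:b]
    p = record.pressure[a:b]
    q_in = record.flow_in[a:b]
    q_out = record.flow_out[a:b]
    phase = record.phase[a:b]

    insp = phase == PHASE_INSPIRE
    expi = ~insp
    if not insp.any() or not expi.any():
        raise ValueError("segment lacks a complete inspiratory/expiratory split")

    pip = float(np.max(p[insp]))

    n_exp = int(expi.sum())
    n_win = max(1, int(round(peep_window_fraction * n_exp)))
    peep = float(np.mean(p[expi][-n_win:]))

    dt = record.dt
    vte = float(np.trapezoid(q_out[expi], dx=dt)) * LPM_TO_MLPS
    inspired = float(np.trapezoid(q_in[insp], dx=dt)) * LPM_TO_MLPS

    thresh = settings.pip_target - rise_band
    above = np.flatnonzero(insp & (p >= thresh))
    rise = float(t[above[0]] - t[0]) if above.size else float("nan")

    return BreathRecord(
        cycle_index=cycle_index,
        start_time=float(t[0]),
        measured_pip=pip,
        measured_peep=peep,
        vte=max(vte, 0.0),
        inspired_volume=max(inspired, 0.0),
        rise_time=rise,
        mean_airway_pressure=float(np.mean(p)),
        spontaneous=spontaneous,
    )


def estimate_compliance(breath: BreathRecord) -> float:
    """Quasi-static compliance estimate VTE / (PIP - PEEP), mL/cmH2O.

    A consistency diagnostic: on a zero-noise run with long plateaus it
    recovers the configured test-lung compliance.
    """
    span = breath.measured_pip - breath.measured_peep
    if span <= 0:
        raise ValueError("measured_pip must exceed measured_peep")
    return breath.vte / span


def breaths_to_frame(records: list[BreathRecord]) -> pd.DataFrame:
    """Breath records as a tidy table, one row per cycle."""
    return pd.DataFrame(
        [
            {
                "cycle_index": r.cycle_index,
                "start_time_s": r.start_time,
                "measured_pip_cmH2O": r.measured_pip,
                "measured_peep_cmH2O": r.measured_peep,
                "vte_mL": r.vte,
                "inspired_volume_mL": r.inspired_volume,
                "rise_time_s": r.rise_time,
                "mean_airway_pressure_cmH2O": r.mean_airway_pressure,
                "spontaneous": r.spontaneous,
            }
            for r in records
        ]
    )


def aggregate_metrics(records: list[BreathRecord]) -> pd.DataFrame:
    """Sample mean and standard deviation (ddof=1) per metric.

    Returns a DataFrame indexed by metric with columns ['mean', 'sd'];
    sd is 0 for a single record.
    """
    if not records:
        raise ValueError("need at least one breath record")
    data = {
        "measured_pip": [r.measured_pip for r in records],
        "measured_peep": [r.measured_peep for r in records],
        "vte": [r.vte for r in records],
        "inspired_volume": [r.inspired_volume for r in records],
        "rise_time": [r.rise_time for r in records],
        "mean_airway_pressure": [r.mean_airway_pressure for r in records],
    }
    rows = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            rows[name] = (float("nan"), float("nan"))
        elif arr.size == 1:
            rows[name] = (float(arr[0]), 0.0)
        else:
            rows[name] = (float(arr.mean()), float(arr.std(ddof=1)))
    return pd.DataFrame(rows, index=["mean", "sd"]).T
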