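"""Fixed-step closed-loop simulation of the ventilator and test lung.

Couples the control stack to the circuit/lung physics: the physics advance
at ``dt_physics`` (explicit Euler on the lung volume), the controller and
sensors run at ``dt_control`` (an integer multiple), and all outputs are
sampled at the control rate.  Runs are deterministic for a given config and
seed: one global NumPy generator drives every stochastic draw (sensor
noise).

The airway node is solved algebraically each physics step.  With the
proportional valve delivering ``Q_in = drive * Q_max`` and the expiratory
limb open, flow balance at the airway gives

    P_aw = P_src + R * (Q_in - Q_out),     Q_out = max(0, (P_aw - PEEP) / R_exp)

where ``P_src = V/C - effort + transient`` is the alveolar-side source
pressure (elastic recoil, minus any patient inspiratory effort, plus any
injected pressure transient).  Solving the linear pair yields passive
exhalation as an exponential decay toward the PEEP setting with time
constant ``(R + R_exp) * C``, and (when the PID holds airway pressure at
the target) inflation as an exponential with time constant ``R * C`` — the
closed forms the unit oracles check.

Scheduled events inject disturbances: SPONTANEOUS_EFFORT subtracts its
magnitude from the alveolar pressure for its duration (a muscle-pressure
pulse, producing the transient PEEP dip a patient-initiated breath causes),
and PRESSURE_TRANSIENT adds its magnitude (an external over-pressure, the
high-pressure-alarm test stimulus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alarms import AlarmEvent, AlarmManager, AlarmRule, default_rules
from .controller import (
    PHASE_INSPIRE,
    BreathController,
    ControllerState,
    PIDGains,
    VentSettings,
    breath_timing,
    control_tick,
)
from .lung import (
    LPM_TO_LPS,
    LPS_TO_LPM,
    CircuitParams,
    LungParams,
    SensorFrame,
    SensorModel,
)
from .metrics import BreathRecord, WaveformRecord, breath_metrics, segment_breaths

__all__ = [
    "EventSpec",
    "SimConfig",
    "SimResult",
    "SimulationError",
    "run_simulation",
    "apply_event",
]

# numeric blow-up guard (cmH2O); far above anything physical in this circuit
PRESSURE_BLOWUP = 500.0


class SimulationError(RuntimeError):
    """Raised when the simulation becomes numerically invalid."""


@dataclass(frozen=True)
class EventSpec:
    """A scheduled disturbance.

    kind is 'SPONTANEOUS_EFFORT' (magnitude = effort depth, cmH2O, subtracted
    from alveolar pressure) or 'PRESSURE_TRANSIENT' (magnitude added,
    cmH2O); active for t in [onset, onset + duration).
    """

    kind: str
    onset: float
    duration: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("SPONTANEOUS_EFFORT", "PRESSURE_TRANSIENT"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("event onset must be >= 0 and duration > 0")

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration


def apply_event(kind: str, magnitude: float, alveolar_pressure: float) -> float:
    """Return the modified alveolar-side source pressure for an active event."""
    if kind == "SPONTANEOUS_EFFORT":
        return alveolar_pressure - magnitude
    if kind == "PRESSURE_TRANSIENT":
        return alveolar_pressure + magnitude
    raise ValueError(f"unknown event kind {kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulation run.

    Exactly one of ``duration`` (s) and ``n_cycles`` must be given;
    ``dt_control`` must be an integer multiple of ``dt_physics``.
    """

    settings: VentSettings
    lung: LungParams
    circuit: CircuitParams = field(default_factory=CircuitParams)
    sensors: SensorModel = field(default_factory=SensorModel)
    gains: PIDGains = field(default_factory=PIDGains)
    dt_physics: float = 0.001
    dt_control: float = 0.005
    duration: float | None = None
    n_cycles: int | None = None
    seed: int = 0
    events: tuple[EventSpec, ...] = ()
    alarm_rules: tuple[AlarmRule, ...] | None = None
    fio2_supply: float = 0.21

    def __post_init__(self) -> None:
        if (self.duration is None) == (self.n_cycles is None):
            raise ValueError("exactly one of duration and n_cycles must be set")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_cycles is not None and self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.dt_physics <= 0 or self.dt_control <= 0:
            raise ValueError("time steps must be > 0")
        ratio = self.dt_control / self.dt_physics
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("dt_control must be an integer multiple of dt_physics")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass
class SimResult:
    """Outputs of one run: sampled waveform, per-breath metrics, alarm log."""

    waveform: WaveformRecord
    breaths: list[BreathRecord]
    alarms: list[AlarmEvent]
    config: SimConfig


def _source_pressure(volume_ml: float, compliance: float, events, t: float) -> float:
    """Alveolar-side source pressure including any active disturbances."""
    p = volume_ml / compliance
    for ev in events:
        if ev.onset <= t < ev.onset + ev.duration:
            p = apply_event(ev.kind, ev.magnitude, p)
    return p


def run_simulation(
    config: SimConfig,
    record_waveform: bool = True,
    on_breath=None,
) -> SimResult:
    """Run the closed loop and return waveform, breath records and alarms.

    With ``record_waveform=False`` only a rolling one-cycle buffer is kept
    (bounded memory for endurance runs); breath records are still produced
    and ``on_breath(record)`` is called as each cycle completes.
    """
    settings = config.settings
    lungp = config.lung
    circ = config.circuit
    sens = config.sensors
    timing = breath_timing(settings)
    t_cycle = timing[0]

    n_sub = round(config.dt_control / config.dt_physics)
    dtc = config.dt_control
    dtp = config.dt_physics

    if config.duration is not None:
        n_ticks = int(math.ceil(config.duration / dtc))
    else:
        # capacity estimate; spontaneous triggers only shorten cycles
        n_ticks = int(math.ceil((config.n_cycles * t_cycle) / dtc)) + 2

    rng = np.random.default_rng(config.seed)
    ctl = BreathController(settings, config.gains)
    rules = (
        list(config.alarm_rules)
        if config.alarm_rules is not None
        else default_rules(settings)
    )
    manager = AlarmManager(rules, settings)

    # physics state
    compliance = lungp.compliance  # mL/cmH2O
    R = lungp.resistance
    R_exp = circ.expiratory_resistance
    q_max = circ.valve_max_flow * LPM_TO_LPS if circ.supply_pressure_ok else 0.0
    volume = settings.peep_setting * compliance  # start equilibrated at PEEP
    p_aw = settings.peep_setting
    q_in = 0.0
    q_out = 0.0
    # flows are reported as averages over the preceding control period (what
    # an integrating flow sensor reports); their rectangle sum then matches
    # the delivered volume exactly even across valve transitions
    q_in_avg = 0.0
    q_out_avg = 0.0
    t = 0.0
    events = config.events

    noise_p = sens.pressure_noise_sd
    noise_q = sens.flow_noise_sd
    insp_side = sens.flow_sensor_side == "inspiratory"

    if record_waveform:
        arr_t = np.empty(n_ticks)
        arr_p = np.empty(n_ticks)
        arr_qi = np.empty(n_ticks)
        arr_qo = np.empty(n_ticks)
        arr_v = np.empty(n_ticks)
        arr_ph = np.empty(n_ticks, dtype=np.int8)
        arr_dr = np.empty(n_ticks)
        arr_ev = np.empty(n_ticks, dtype=bool)
        arr_am = np.empty(n_ticks, dtype=np.uint16)
    buf: list[tuple] = []  # rolling one-cycle buffer in streaming mode

    spont_ticks: set[int] = set()
    cycle_start_tick = 0
    breaths: list[BreathRecord] = []
    k = 0

    def _finish_cycle(end_tick: int, spontaneous_next: bool) -> None:
        """Streaming mode: compute metrics for the cycle ending at end_tick."""
        nonlocal cycle_start_tick
        if not buf:
            return
        cols = list(zip(*buf))
        mini = WaveformRecord(
            time=np.asarray(cols[0]),
            pressure=np.asarray(cols[1]),
            flow_in=np.asarray(cols[2]),
            flow_out=np.asarray(cols[3]),
            volume=np.asarray(cols[4]),
            phase=np.asarray(cols[5], dtype=np.int8),
            valve_drive=np.asarray(cols[6]),
            expiratory_valve_open=np.asarray(cols[7], dtype=bool),
        )
        try:
            rec = breath_metrics(
                mini,
                (0, len(mini)),
                settings,
                cycle_index=len(breaths),
                spontaneous=cycle_start_tick in spont_ticks,
            )
        except ValueError:
            rec = None  # cycle with no clean insp/exp split (e.g. override)
        if rec is not None:
            breaths.append(rec)
            manager.update_breath(rec)
            if on_breath is not None:
                on_breath(rec)
        buf.clear()
        cycle_start_tick = end_tick

    while k < n_ticks:
        # --- sense (from the state at the end of the last physics step)
        pr = sens.pressure_gain * p_aw + sens.pressure_offset
        if noise_p > 0:
            pr += rng.normal(0.0, noise_p)
        fl = (q_in_avg if insp_side else q_out_avg) * LPS_TO_LPM
        if noise_q > 0:
            fl += rng.normal(0.0, noise_q)
        frame = SensorFrame(t, pr, fl, config.fio2_supply)
        manager.update_tick(frame)

        # --- control
        out = ctl.tick(frame, dtc)
        if out.new_cycle_started:
            if record_waveform:
                if out.spontaneous:
                    spont_ticks.add(k)
                cycle_start_tick = k
            else:
                if out.spontaneous:
                    spont_ticks.add(k)
                _finish_cycle(k, out.spontaneous)
            if config.n_cycles is not None and ctl.state.cycle_index >= config.n_cycles:
                n_ticks = k + 1  # keep the boundary sample, then stop

        # --- record at control rate
        if record_waveform:
            arr_t[k] = t
            arr_p[k] = pr
            arr_qi[k] = q_in_avg * LPS_TO_LPM
            arr_qo[k] = q_out_avg * LPS_TO_LPM
            arr_v[k] = volume
            arr_ph[k] = ctl.state.phase
            arr_dr[k] = out.valve_drive
            arr_ev[k] = out.expiratory_valve_open
            arr_am[k] = manager.active_mask()
        else:
            buf.append(
                (
                    t,
                    pr,
                    q_in_avg * LPS_TO_LPM,
                    q_out_avg * LPS_TO_LPM,
                    volume,
                    ctl.state.phase,
                    out.valve_drive,
                    out.expiratory_valve_open,
                )
            )

        if config.n_cycles is not None and ctl.state.cycle_index >= config.n_cycles:
            k += 1
            break

        # --- physics substeps over one control period
        drive = out.valve_drive
        exp_open = out.expiratory_valve_open
        q_in_sum = 0.0
        q_out_sum = 0.0
        for _ in range(n_sub):
            q_in = drive * q_max
            p_src = _source_pressure(volume, compliance, events, t)
            if exp_open:
                # airway node with both limbs: solve the linear pair
                p_cand = (p_src + R * q_in + (R / R_exp) * settings.peep_setting) / (
                    1.0 + R / R_exp
                )
                if p_cand > settings.peep_setting:
                    p_aw = p_cand
                    q_out = (p_aw - settings.peep_setting) / R_exp
                else:
                    q_out = 0.0
                    p_aw = p_src + R * q_in
            else:
                q_out = 0.0
                p_aw = p_src + R * q_in
            volume += (q_in - q_out) * 1000.0 * dtp
            if volume < 0.0:
                volume = 0.0
            q_in_sum += q_in
            q_out_sum += q_out
            t += dtp
        q_in_avg = q_in_sum / n_sub
        q_out_avg = q_out_sum / n_sub
        if not math.isfinite(volume) or abs(p_aw) > PRESSURE_BLOWUP:
            raise SimulationError(
                f"numeric blow-up at t={t:.3f}s: volume={volume}, pressure={p_aw}"
            )
        k += 1

    if record_waveform:
        waveform = WaveformRecord(
            time=arr_t[:k],
            pressure=arr_p[:k],
            flow_in=arr_qi[:k],
            flow_out=arr_qo[:k],
            volume=arr_v[:k],
            phase=arr_ph[:k],
            valve_drive=arr_dr[:k],
            expiratory_valve_open=arr_ev[:k],
            alarm_mask=arr_am[:k],
        )
        segments = segment_breaths(waveform) if k > 1 else []
        breaths = [
            breath_metrics(
                waveform,
                seg,
                settings,
                cycle_index=i,
                spontaneous=seg[0] in spont_ticks,
            )
            for i, seg in enumerate(segments)
        ]
        for rec in breaths:
            manager.update_breath(rec)
            if on_breath is not None:
                on_breath(rec)
    else:
        waveform = WaveformRecord(
            time=np.zeros(0),
            pressure=np.zeros(0),
            flow_in=np.zeros(0),
            flow_out=np.zeros(0),
            volume=np.zeros(0),
            phase=np.zeros(0, dtype=np.int8),
            valve_drive=np.zeros(0),
            expiratory_valve_open=np.zeros(0, dtype=bool),
        )

    manager.finalize(t)
    return SimResult(waveform, breaths, manager.log, config)
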