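"""Single-compartment test-lung mechanics and the pneumatic circuit.

The mechanical test lung is the classic linear R/C model: a single elastic
compartment of compliance ``C`` (mL/cmH2O) filled through an airway
resistance ``R`` (cmH2O/(L/s)).  Driving the airway at a constant pressure
``P`` inflates the compartment exponentially with time constant ``tau = R*C``
toward the equilibrium volume ``C*P``.  The circuit around the lung consists
of a proportional valve on the inspiratory limb (modelled as an ideal flow
source, drive in [0, 1] scaling a maximum flow), and a solenoid valve in
series with a mechanical spring-loaded PEEP valve on the expiratory limb
(modelled as an ideal threshold valve: zero flow at or below the PEEP
setting, linear conductance above it).

Units
-----
Pressures are cmH2O, volumes mL at the dataclass surface, flows L/s inside
the physics and L/min on sensor/display surfaces, time seconds.  Compliance
is mL/cmH2O so that ``volume_mL / compliance`` is directly a pressure in
cmH2O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LungParams",
    "CircuitParams",
    "LungState",
    "SensorModel",
    "SensorFrame",
    "lung_flow",
    "step_lung",
    "expiratory_flow",
    "read_sensors",
    "calibrate_pressure_sensor",
]

LPM_TO_LPS = 1.0 / 60.0  # L/min -> L/s
LPS_TO_LPM = 60.0

# Physics integration step bounds (s); explicit Euler is validated against
# the exponential closed form at 1 ms and remains stable for any
# tau = R*C well above the step.
MAX_PHYSICS_DT = 0.010


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LungParams:
    """Test-lung mechanics.

    Parameters
    ----------
    compliance : float
        Volume change per unit distending pressure, mL/cmH2O.
    resistance : float
        Airway resistance, cmH2O/(L/s).
    residual_capacity : float, optional
        Volume offset at zero distending pressure, mL.  Stored and reported
        (the pediatric QuickLung Jr. has an uncompensated 400 mL residual)
        but does not enter the linear pressure-volume relation.
    """

    compliance: float
    resistance: float
    residual_capacity: float = 0.0

    def __post_init__(self) -> None:
        if not (self.compliance > 0):
            raise ValueError(f"compliance must be > 0, got {self.compliance}")
        if not (self.resistance > 0):
            raise ValueError(f"resistance must be > 0, got {self.resistance}")
        if self.residual_capacity < 0:
            raise ValueError("residual_capacity must be >= 0")

    @property
    def time_constant(self) -> float:
        """tau = R*C in seconds (compliance converted to L/cmH2O)."""
        return self.resistance * self.compliance / 1000.0


@dataclass(frozen=True)
class CircuitParams:
    """Pneumatic circuit around the lung.

    valve_max_flow is the proportional-valve flow at full drive in L/min
    (hardware spec range 0-100 L/min); the 50 psi supply is treated as an
    ideal source, represented only by the ``supply_pressure_ok`` flag.
    """

    valve_max_flow: float = 100.0
    expiratory_resistance: float = 5.0
    tubing_compliance: float = 0.0
    supply_pressure_ok: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.valve_max_flow <= 100):
            raise ValueError(
                f"valve_max_flow must be in (0, 100] L/min, got {self.valve_max_flow}"
            )
        if not (self.expiratory_resistance > 0):
            raise ValueError("expiratory_resistance must be > 0")
        if self.tubing_compliance < 0:
            raise ValueError("tubing_compliance must be >= 0")


@dataclass(frozen=True)
class LungState:
    """Instantaneous state of the lung compartment.

    volume_above_residual is mL above the residual capacity; airway_pressure
    is the pressure at the airway opening (sensor location) in cmH2O; flows
    are L/s, positive in the direction of normal operation.
    """

    volume_above_residual: float = 0.0
    airway_pressure: float = 0.0
    flow_in: float = 0.0
    flow_out: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("volume_above_residual", "airway_pressure", "flow_in", "flow_out", "time"):
            _require_finite(name, getattr(self, name))
        if self.volume_above_residual < 0:
            raise ValueError("volume_above_residual must be >= 0")

    def alveolar_pressure(self, params: LungParams) -> float:
        """Elastic recoil pressure V/C in cmH2O."""
        return self.volume_above_residual / params.compliance


@dataclass(frozen=True)
class SensorModel:
    """Affine-plus-Gaussian sensor model.

    reading = gain * truth + offset + N(0, sd).  A miscalibrated gain/offset
    reproduces the few-cmH2O deviations seen with drifted pressure sensors.
    """

    pressure_noise_sd: float = 0.1
    flow_noise_sd: float = 0.5
    pressure_gain: float = 1.0
    pressure_offset: float = 0.0
    sample_dt: float = 0.005
    flow_sensor_side: str = "expiratory"

    def __post_init__(self) -> None:
        if self.pressure_noise_sd < 0 or self.flow_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (self.sample_dt > 0):
            raise ValueError("sample_dt must be > 0")
        if self.flow_sensor_side not in ("inspiratory", "expiratory"):
            raise ValueError("flow_sensor_side must be 'inspiratory' or 'expiratory'")


@dataclass(frozen=True)
class SensorFrame:
    """One sampled frame of the display variables."""

    time: float
    pressure_reading: float  # cmH2O
    flow_reading: float  # L/min, from the configured sensor side
    fio2_reading: float = 0.21  # fraction


def lung_flow(applied_pressure: float, state: LungState, params: LungParams) -> float:
    """Flow into the lung (L/s) when `applied_pressure` drives the airway.

    Q = (P_applied - V/C) / R with the sign positive into the lung.
    """
    p = _require_finite("applied_pressure", applied_pressure)
    recoil = state.alveolar_pressure(params)
    return (p - recoil) / params.resistance


def step_lung(
    state: LungState, applied_pressure: float, dt: float, params: LungParams
) -> LungState:
    """Advance the pressure-driven lung by one explicit-Euler step.

    dt must be in (0, 10] ms; at 1 ms the accumulated error against the
    exact exponential solution stays below 1% of the asymptotic volume
    change C*dP for any time constant in the test-lung grid.
    """
    if not (0 < dt <= MAX_PHYSICS_DT):
        raise ValueError(f"dt must be in (0, {MAX_PHYSICS_DT}] s, got {dt}")
    q = lung_flow(applied_pressure, state, params)  # L/s
    new_volume = state.volume_above_residual + q * 1000.0 * dt
    if new_volume < 0.0:
        new_volume = 0.0
    return replace(
        state,
        volume_above_residual=new_volume,
        airway_pressure=float(applied_pressure),
        flow_in=max(q, 0.0),
        flow_out=max(-q, 0.0),
        time=state.time + dt,
    )


def expiratory_flow(
    airway_pressure: float,
    peep_setting: float,
    valve_open: bool,
    params: CircuitParams,
) -> float:
    """Flow (L/s) escaping through the expiratory solenoid + PEEP valve.

    The mechanical PEEP valve is an ideal threshold: no flow at or below the
    PEEP setting, linear conductance above it; the valve is one-way so flow
    is never negative.
    """
    p = _require_finite("airway_pressure", airway_pressure)
    if not valve_open or p <= peep_setting:
        return 0.0
    return (p - peep_setting) / params.expiratory_resistance


def read_sensors(
    state: LungState,
    model: SensorModel,
    rng: np.random.Generator,
    fio2: float = 0.21,
) -> SensorFrame:
    """Sample the sensors: affine transform plus Gaussian noise.

    With the same generator state two calls return identical frames; zero
    noise, unit gain and zero offset return the true values.
    """
    p_noise = rng.normal(0.0, model.pressure_noise_sd) if model.pressure_noise_sd > 0 else 0.0
    q_noise = rng.normal(0.0, model.flow_noise_sd) if model.flow_noise_sd > 0 else 0.0
    pressure = model.pressure_gain * state.airway_pressure + model.pressure_offset + p_noise
    true_flow = state.flow_in if model.flow_sensor_side == "inspiratory" else state.flow_out
    flow = true_flow * LPS_TO_LPM + q_noise
    return SensorFrame(
        time=state.time,
        pressure_reading=pressure,
        flow_reading=flow,
        fio2_reading=fio2,
    )


def calibrate_pressure_sensor(pairs) -> tuple[float, float]:
    """Least-squares (gain, offset) mapping raw sensor readings to cmH2O.

    `pairs` is an iterable of (raw_reading, known_pressure).  Two points give
    the exact interpolating line; more points give the least-squares fit.
    Degenerate input (all raw readings equal) is rejected.
    """
    pts = [(float(r), float(p)) for r, p in pairs]
    if len(pts) < 2:
        raise ValueError("need at least two calibration pairs")
    raw = np.array([r for r, _ in pts])
    known = np.array([p for _, p in pts])
    if np.ptp(raw) == 0:
        raise ValueError("calibration pairs are degenerate: all raw readings equal")
    gain, offset = np.polyfit(raw, known, 1)
    return float(gain), float(offset)
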