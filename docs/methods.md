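# Methods

This note documents the models, numerical choices and design decisions
behind pvpsim, and what the simulator's passing tests do and do not say
about physical hardware.

## Physical model

**Lung.** A linear single-compartment model: volume above residual capacity
*V* (mL), compliance *C* (mL/cmH₂O), airway resistance *R* (cmH₂O/(L/s)),
alveolar recoil pressure *V*/*C*.  `residual_capacity` (e.g. the 400 mL of
an uncompensated pediatric test lung) is stored and reported but does not
enter the dynamics — the pressure–volume relation is linear by assumption,
and nonlinear compliance, multi-compartment mechanics and flow-dependent
resistance are out of scope.  Consequence: simulated volumes at a given
pressure span are exactly *C*·ΔP in the quasi-static limit, with none of
the compliance roll-off a real test lung shows near its volume limits.

**Circuit.** The inspiratory proportional valve is an ideal flow source,
`Q_in = drive · valve_max_flow` with drive ∈ [0, 1] and `valve_max_flow`
defaulting to 100 L/min (the hardware valve's specified range; the supply
is a regulated 50 psi source, ~3500 cmH₂O, so airway back-pressure of tens
of cmH₂O changes the deliverable flow negligibly and the valve's own
pressure–flow curve is not modelled).  The expiratory solenoid plus
mechanical PEEP valve is an ideal threshold element: zero flow at or below
the PEEP setting, linear conductance `1/expiratory_resistance`
(default 5 cmH₂O/(L/s)) above it; spring dynamics are not modelled.
`tubing_compliance` is carried as a parameter for completeness but the
default circuit treats the airway node as massless: flow balance

    P_aw = P_alv + R·(Q_in − Q_out),   Q_out = max(0, (P_aw − PEEP)/R_exp)

is solved algebraically each step (a linear 2×2 when the expiratory valve
is open, with a one-way check against the PEEP threshold).

Two closed forms follow and serve as oracles in the tests: passive
exhalation decays exponentially toward the PEEP setting with
τ = (R + R_exp)·C, and inflation under a controller that holds airway
pressure at the target fills the lung with τ = R·C.

**Integration.** Explicit Euler at `dt_physics` = 1 ms (hard-capped at
10 ms).  At 1 ms the worst grid corner (τ = 25 ms at C=5, R=5) stays within
1% of the exact exponential; the endurance mode's 10 ms step is documented
coarse operation (τ of the midpoint condition is 400–500 ms, so the step is
still ≥ 40× inside the dynamics; the plateau overshoot it introduces is
≈ 0.9 cmH₂O and drift, the endurance metric, is unaffected).

**Sensors.** Affine-plus-Gaussian: reading = gain·truth + offset + N(0, σ),
with σ = 0.1 cmH₂O (pressure) and 0.5 L/min (flow) by default, gain 1,
offset 0.  Calibration (`calibrate_pressure_sensor`) is a least-squares
line through (raw, known-pressure) pairs.  The flow channels in recorded
waveforms are averages over the preceding control period — what an
integrating flow sensor reports — so that their rectangle sum equals the
delivered volume exactly even across the instantaneous valve transitions;
instantaneous sampling at 200 Hz would alias away up to ~10% of the
expiratory spike of a stiff, low-resistance lung.  One flow sensor is
assumed; it can sit on either limb (`flow_sensor_side`, default
expiratory, which is the displayed "flow out"; the inspiratory placement
is also supported since the hardware documentation describes both).

## Controller

A timed-cycle, two-phase state machine at `dt_control` = 5 ms (200 Hz; the
control rate is a design choice — it resolves a 300 ms ramp with 60
samples).  INSPIRE: expiratory valve closed, PID drives the proportional
valve toward the pressure target.  EXPIRE: drive 0, expiratory valve open.
Phase boundaries come from RR and I:E ratio (or a directly set inspiratory
time).  Settings are validated against the device label ranges
(PIP 15–60, PEEP 5–25, RR 10–40, I:E 1:1–1:3) by default;
`strict=False` lifts the label validation for engineering/diagnostic runs
(used by the quasi-static compliance-recovery tests, whose slow lungs need
plateaus longer than any clinical cycle allows).

**PID.**  drive = clamp(fa·kp·e + ki·∫e dt + kd·dê/dt, 0, 1), where
e = target − measured pressure, fa is the clinician's flow-adjustment
factor (it scales the proportional gain, which is how ramp speed is tuned
at the bedside), and ê is a low-pass-filtered error (τ = 20 ms) so the
derivative never acts on raw noise.  Three shaping elements matter:

- **Setpoint ramp.** The inspiratory target rises linearly from PEEP to
  PIP over `setpoint_ramp_time` = 0.2 s, then holds.  A step target makes
  the loop fight the direct resistive feed-through R·Q_in: the error
  collapses the instant flow starts, which no fixed PI gain set can track
  across a 10× range of C and R without either ringing (stiff, fast lungs)
  or stalling (large, slow lungs).  The ramp bounds the transient error so
  one gain set serves the whole test envelope.
- **Anti-windup.** The integral freezes when the output is saturated in
  the error's direction, is clamped so |ki·∫e| ≤ `integral_clamp` = 1
  drive unit, and back-calculates (tracks the clamped output with
  τ = 50 ms) so windup accumulated during a saturated ramp bleeds off in a
  few control periods instead of pinning the valve.
- **Asymmetric unwind.** Negative error (pressure above target) integrates
  `unwind_ratio` = 6× faster than positive error.  Overshoot is the
  clinically dangerous direction (barotrauma); biasing the integral to
  shed drive quickly after the target is crossed cuts peak-pressure
  overshoot at the low-resistance grid corners from ~15–20% to under 5%
  at the cost of a slightly conservative plateau approach.

**Default gains** kp = 0.010, ki = 1.5, kd = 0 (drive per cmH₂O; the
derivative destabilizes this plant because the resistive feed-through makes
measured pressure jump discontinuously with drive, so damping comes from
the setpoint ramp and the asymmetric integral instead).  The gains are not
taken from any hardware documentation — none are published — and were tuned
in closed loop against three simultaneous constraints: ≤ 300 ms
steady-state rise at the midpoint condition (C=20, R=20, PIP 30, PEEP 5);
peak-pressure deviation within single digits over the full C ∈ {5,20,50} ×
R ∈ {5,20,50} grid; and pediatric (C=10, R=25, PIP 20, t_insp 0.6 s)
tracking within 1 cmH₂O.  The tuning sweep evaluated (kp, ki,
setpoint_ramp_time, unwind_ratio) on those conditions and picked the
combination with the largest margin on the grid deviation; all four knobs
are exposed in the YAML config.  With these defaults the measured numbers
are ≈ 200 ms rise, ≈ 4.9% worst-case grid deviation (at C=5, R=5), and
≈ 0.4 cmH₂O mean pediatric PIP error with ≈ 128 mL inspired volume.

**Triggering (SIMV).** A patient effort is detected when, during EXPIRE and
after a refractory window of 20% of the expiratory time, measured pressure
stays more than `trigger_sensitivity` (default 1 cmH₂O) below the set PEEP
for 3 consecutive control ticks; detection resets the breath cycle
immediately.  Debounce count and refractory fraction are design constants
(no published values): 3 ticks = 15 ms rejects single-sample noise, and the
refractory window rejects the valve-opening transient at the start of
expiration.  If a trigger and the scheduled cycle end coincide, the
scheduled cycle wins and the breath is not flagged spontaneous.  Note the
physics: while expiratory flow is still running, an alveolar effort is
attenuated at the airway sensor by the R/R_exp divider; the full dip (and
hence reliable triggering) appears once the lung has reached its PEEP hold
— which is also when real trigger devices are applied.

**Safety override.** Pressure above `hapa_limit` (default
min(PIP + 15, 60) cmH₂O) for 3 consecutive ticks forces drive 0 and the
expiratory valve open, and raises the high-priority alarm.  The override
drops as soon as pressure falls below the limit; the controller then holds
EXPIRE until the next scheduled cycle boundary, so one corrupted cycle is
sacrificed rather than resuming mid-inspiration.

## Alarms

High-pressure, low-FiO₂ and technical (non-finite sensor data) conditions
are evaluated every control tick, so their detection latency is bounded by
persistence × dt_control (15 ms at defaults).  Breath-statistics conditions
— low PIP, PEEP not met, hypo-/hyperventilation (measured rate from recent
cycle intervals; collapsed VTE against a rolling median), obstruction (VTE
collapse while PIP is at target), disconnect/leak (collapsed plateau or
inspired/exhaled volume mismatch > 25%) — are evaluated once per completed
breath with a 3-breath persistence.  All thresholds are declared defaults,
configurable per rule; none are taken from hardware documentation.  Alarms
are episodic (one onset, at most one clear, episodes of one type never
overlap) and can latch until acknowledged.

## Simulation engine

Physics at `dt_physics`, controller and sensors at `dt_control` (an integer
multiple; flows are averaged over the control period as described above).
One `numpy` generator seeded once per run drives all noise, so identical
config + seed gives bit-identical outputs.  The clock is idealized (no
jitter); real-time pacing is out of scope.  Scheduled events perturb the
alveolar-side source pressure: a spontaneous effort subtracts its magnitude
(a one-parameter muscle-pressure pulse — chosen over modelling the actual
trigger hardware because the observable, a transient PEEP dip, is the same),
a pressure transient adds it (with the expiratory valve closed this adds
exactly the magnitude to airway pressure; with flow, it divides across the
resistances, which is the physical behaviour of an external pressure
source).  Numeric blow-up (non-finite volume or |pressure| > 500 cmH₂O) is
reported as an error, never clipped silently.

Endurance runs stream per-cycle metrics from a rolling one-cycle buffer, so
memory is independent of cycle count.  The zero-noise, no-event endurance
configuration additionally runs as a numba-compiled kernel that transcribes
the engine's tick loop statement for statement; a test holds the two paths
to per-cycle agreement within 1e-6, and noisy or evented configurations
always take the reference Python path.

## Problem sizes and test design

The test suite runs closed-loop simulations of 3–30 s (6–60 breath cycles)
per case and a 70,000-cycle endurance run at the coarse 10 ms step; the
whole suite completes in well under a minute on one core.  Measurement
windows discard 5 settle cycles — the report deviations are insensitive to
settling beyond 3 cycles, which a test asserts.  The pediatric statistics
use 300 cycles, matching the "several hundred" scale of bench practice.

The quasi-static compliance diagnostic (`estimate_compliance`,
VTE/(PIP−PEEP)) is validated with gentle breaths: setpoint ramp
max(1 s, 2τ) and plateaus ≥ 5.5τ on both phases.  With clinical-speed
breaths the metric is biased low because measured PIP is a maximum and
carries the ramp's resistive transient; the diagnostic protocol, not the
clinical one, is the stated scope of the 5% recovery guarantee.

## What passing tests do and do not show

The simulator's conditions are idealized: linear lung, ideal valves, ideal
supply, Gaussian sensor noise, no tubing dynamics, no humidity or gas
composition effects, no timing jitter.  Meeting the ramp, deviation,
latency and endurance bounds here demonstrates that the control logic and
alarm logic are correct and well-tuned for the modelled plant — it does not
certify hardware performance, where valve curves, circuit compliance,
sensor drift and test-lung nonlinearity (e.g. the pediatric lung's residual
capacity) all shift the numbers.  The pediatric inspired-volume figure in
particular sits close to its hardware counterpart partly because the
inspiratory time (0.6 s ≈ 2.4 lung time constants) — not controller detail —
dominates delivered volume in this configuration.

## Known limitations

- No volume-controlled, pressure-supported or CPAP modes (matching the
  device's released feature set); SIMV semantics are limited to
  phase-shift-on-trigger, with no mandatory-breath scheduling windows.
- FiO₂ is a static pass-through channel; gas blending is not modelled.
- The breath-cycle clock accumulates floating-point period error of one
  control tick every few hundred cycles (cycle boundaries may land one
  5 ms tick late); per-breath metrics are unaffected.
- Alarm-mask annotations in recorded waveforms cover tick-rate alarms
  only; breath-rate alarm episodes appear in the alarm log with onset
  times at the offending breath's start.
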