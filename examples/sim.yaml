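# Example simulation config: adult midpoint bench condition.
# Run with:  pvpsim simulate --config examples/sim.yaml -o run.h5
# Any CLI flag (--pip, --peep, --rr, --ie/--tinsp, -C, -R, ...) overrides
# the corresponding value here.

ventilator:
  pip_target: 30.0          # target peak inspiratory pressure, cmH2O (15-60)
  peep_setting: 5.0         # mechanical PEEP valve setting, cmH2O (5-25)
  respiratory_rate: 15.0    # breaths/min (10-40)
  ie_ratio: 2.0             # the x of "1:x"; alternatively set t_insp (s)
  t_insp: null
  flow_adjustment: 1.0      # scales the PID proportional gain (ramp speed)
  trigger_sensitivity: 1.0  # breath-effort dip below PEEP that triggers, cmH2O
  hapa_limit: 45.0          # high-airway-pressure alarm limit, cmH2O (<= 60)
  fio2_set: 0.21            # set inspired-oxygen fraction

lung:
  compliance: 20.0          # mL/cmH2O
  resistance: 20.0          # cmH2O/(L/s)
  residual_capacity: 0.0    # mL; volume offset, reported but not dynamic

circuit:
  valve_max_flow: 100.0     # proportional-valve flow at full drive, L/min
  expiratory_resistance: 5.0  # cmH2O/(L/s) through solenoid + PEEP valve
  tubing_compliance: 0.0    # mL/cmH2O (lumped; not part of the dynamics)
  supply_pressure_ok: true  # 50 psi supply present

sensors:
  pressure_noise_sd: 0.1    # cmH2O
  flow_noise_sd: 0.5        # L/min
  pressure_gain: 1.0        # affine miscalibration: reading = gain*p + offset
  pressure_offset: 0.0
  sample_dt: 0.005          # s
  flow_sensor_side: expiratory   # or inspiratory

gains:                      # PID (drive per cmH2O); see docs/methods.md
  kp: 0.010
  ki: 1.5
  kd: 0.0
  integral_clamp: 1.0
  deriv_filter_tau: 0.02
  tracking_tau: 0.05
  setpoint_ramp_time: 0.2
  unwind_ratio: 6.0

sim:
  dt_physics: 0.001         # s; explicit-Euler lung step
  dt_control: 0.005         # s; controller/sensor period (integer multiple)
  duration: 30.0            # s; or set n_cycles instead
  n_cycles: null
  seed: 1
  fio2_supply: 0.21

events: []                  # e.g.
# events:
#   - kind: SPONTANEOUS_EFFORT   # patient effort: dips alveolar pressure
#     onset: 15.0
#     duration: 0.4
#     magnitude: 3.0             # cmH2O
#   - kind: PRESSURE_TRANSIENT   # external over-pressure
#     onset: 21.0
#     duration: 0.2
#     magnitude: 20.0
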