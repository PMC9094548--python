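# pvpsim

A closed-loop, pure-software simulator of an open-source pressure-controlled
ventilator.  It reimplements the device's control stack — breath-cycle state
machine, PID pressure control with flow-adjustment gain scaling, spontaneous
breath triggering (SIMV), a high-airway-pressure safety override and the
standard alarm set — and runs it against a physics model of the pneumatic
circuit and a single-compartment mechanical test lung.  Everything the
hardware bench tests measure (pressure ramps, plateau tracking, alarm
latencies, tidal volumes, endurance stability) can be exercised and tested
in silico, deterministically and in seconds.

It is intended for people studying or developing ventilation control
software: control engineers tuning gains before touching hardware, students
of respiratory mechanics, and developers who need a reproducible test
harness for ventilator logic.

## Model

The test lung is the linear single-compartment R/C model: compliance *C*
(mL/cmH₂O), airway resistance *R* (cmH₂O/(L/s)), alveolar recoil pressure
*P*ₐₗᵥ = *V*/*C*.  The inspiratory limb holds a proportional valve modelled
as an ideal flow source (*Q*ᵢₙ = drive · *Q*ₘₐₓ, drive ∈ [0, 1]); the
expiratory limb holds a solenoid in series with a mechanical PEEP valve,
modelled as an ideal threshold valve with linear conductance above the PEEP
setting.  Flow balance at the airway node,

    P_aw = P_alv + R·(Q_in − Q_out),    Q_out = max(0, (P_aw − PEEP)/R_exp),

is solved algebraically each physics step and the lung volume integrated by
explicit Euler (1 ms default).  Passive exhalation is then exactly the
exponential decay toward PEEP with time constant (*R* + *R*ₑₓₚ)·*C*, and
inflation under a pressure-holding controller approaches the target with
time constant *R*·*C* — both verified against closed forms in the tests.

During inspiration a PID loop (with setpoint ramp, anti-windup and an
asymmetric integral that unwinds faster on overshoot) drives the valve so
airway pressure tracks the set PIP; at the set inspiratory time the
controller switches to passive expiration down to PEEP.  A sustained
pressure dip below PEEP during expiration triggers an early cycle; a
sustained pressure above the alarm limit forces the valve shut, opens the
expiratory limb, and raises a high-priority alarm.  See
[docs/methods.md](docs/methods.md) for assumptions, parameters and tuning.

## Worked example

Simulate the adult midpoint bench condition (C = 20 mL/cmH₂O,
R = 20 cmH₂O/(L/s), PIP 30, PEEP 5, RR 15, I:E 1:2) for 30 s:

```
pvpsim simulate --config examples/sim.yaml --seed 1 -o run.h5
```

which prints the per-breath summary (mean ± sd over the run):

```
                            mean        sd
measured_pip           30.516343  0.069665
measured_peep           5.036872  0.009349
vte                   473.063361  0.181266
inspired_volume       472.967157  0.809959
rise_time               0.204286  0.003450
mean_airway_pressure   13.227932  0.006732
```

Read it: peak inspiratory pressure tracks the 30 cmH₂O target to within
0.5 cmH₂O (the sd reflects the default 0.1 cmH₂O sensor noise), end-expiratory
pressure holds the 5 cmH₂O PEEP valve setting, each breath delivers ≈473 mL
(just under the quasi-static limit C·(PIP−PEEP) = 500 mL, because the
1.33 s inspiration is 3.3 lung time constants), and pressure reaches the
target in ≈204 ms — inside the 300 ms ramp budget.  `pvpsim analyze run.h5`
recomputes the same table from the stored waveform.

Other subcommands: `pvpsim eua --grid default -o report.csv` runs the
3×3 C×R regulatory-style grid plus a pediatric condition and reports
per-condition PIP deviation and pass/fail flags; `pvpsim endurance
--cycles 70000 --dt-physics 0.01 -o endurance.csv` streams a long-run
stability test.

As a library:

```python
from pvpsim import SimConfig, VentSettings, LungParams, run_simulation

config = SimConfig(
    settings=VentSettings(pip_target=30, peep_setting=5,
                          respiratory_rate=15, ie_ratio=2.0),
    lung=LungParams(compliance=20, resistance=20),
    duration=30.0, seed=1,
)
result = run_simulation(config)       # waveform, breath records, alarm log
print(result.breaths[-1].measured_pip)
```

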