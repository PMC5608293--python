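# microtherm

A fully virtual re-implementation of a feedback-controlled microwave
hyperthermia instrument for small-animal experiments: a modified kitchen
microwave oven whose 2450 MHz / 1000 W magnetron is switched by a relay to
heat an exteriorised rat liver lobe to mild-hyperthermia targets
(40–44 °C), while the rest of the animal is protected by a grounded
aluminium-foil shield and a 100 ml water container absorbs most of the
magnetron output.

The package is aimed at people studying or teaching thermal dosimetry and
bang-bang temperature control: it lets you reproduce the instrument's
published characterisation numbers on a desk, stress the control loop with
sensor noise and discharge artifacts the physical rig was built to
suppress, and explore tissue-slab temperature homogeneity with a
steady-state conduction solver.

## The model

**Plant.** The heated lobe is a lumped compartment with a piecewise-constant
gross heating rate and a constant loss rate,

```
dT/dt = relay(t) · h(T) − [T > T_chamber] · L0
```

where `h(T) = h_i` on temperature interval `i` and `L0` is the loss rate to
the chamber. Under continuous power the observable ramp slope is the net
rate `s_i = h_i − L0`; at a bang-bang plateau the relay on-fraction is
exactly `D = L0 / h` for the interval feeding the plateau from below. The
published characterisation (net slopes 3.375 / 0.291 / 0.136 °C/s over
30–40 / 40–42 / 42–44 °C, duty cycle 20.5 % at the 42 °C plateau) therefore
inverts in closed form:

```
L0  = D·s₂ / (1 − D) = 0.0750 °C/s
h_i = s_i + L0       = 3.450, 0.366, 0.211 °C/s
```

A shielded-body compartment drifts slowly downward (the chamber is at room
temperature) and a passive water-trap compartment integrates absorbed
magnetron energy.

**Controller.** The virtual instrument samples needle thermocouples at
10 kHz with 0.01 °C resolution, smooths them with a 10-sample moving
average, and drives the relay through a 0.1 °C hysteresis band anchored at
the stage setpoint (on below `setpoint − 0.1`, off at `setpoint`). A
protocol is a list of stages `(setpoint, dwell)`; the dwell clock starts at
the first filtered crossing of the setpoint.

**Analytics.** Ramp segmentation between breakpoints, OLS slope/R² fits,
relay duty cycle from the event log, plateau stability, replicate
aggregation (mean ± sample SD on a common grid), and the calibration
inverse above.

**Bioheat solver.** `−k∇²T = q` on a 2 × 2 cm tissue slab with 20 °C
Dirichlet walls, for uniform (non-directional cavity) versus exponentially
attenuated (directional) power deposition, scaled so the core sits at
40 °C — a computable version of the claim that non-directional exposure
blunts the in-tissue thermal gradient.

## Worked example

```sh
microtherm simulate --seed 1 --out-trace trace.csv --out-relay relay.csv
microtherm analyze --trace trace.csv --relay relay.csv --out report.json
```

simulates the reference protocol (noiseless sensing, stages 40/42/44 °C
with 20 s dwells, 30 °C initial lobe) and re-measures the instrument's
characterisation from the recorded trace. The report contains:

```
segment 30–40 °C: slope 3.375 °C/s, R² 1.000   (published 3.375)
segment 40–42 °C: slope 0.291 °C/s, R² 1.000   (published 0.291)
segment 42–44 °C: slope 0.136 °C/s, R² 1.000   (published 0.136)
plateau 42 °C:    duty 0.2026, sd 0.029 °C     (published duty 20.5 %)
```

The plateau SD of ~0.03 °C and maximum band excursion of one quantization
step (0.01 °C) quantify the "very stable temperature" the hysteresis
controller holds; the 42 °C duty of 20.3 % against the analytic
`L0/h₂ = 20.5 %` shows the closed loop realising the calibrated energy
balance. `microtherm calibrate` prints the closed-form inverse directly:

```
L0 = 0.0750 °C/s; gross rates 3.4500, 0.3660, 0.2110 °C/s -> plant.toml
```

The library mirrors the CLI one-to-one (`run_experiment`, `segment_trace`,
`fit_segment`, `duty_cycle`, `calibrate_from_observations`, `solve_steady`,
…); see the module docstrings.

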