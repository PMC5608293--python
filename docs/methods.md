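# Methods

## Scope and intent

`microtherm` is a virtual rig: every quantity it reports is produced by
simulating the closed loop (plant → sensors → filter → relay → plant) and
re-measuring the outputs with the analysis stage. The published
characterisation numbers of the physical instrument enter only once, as the
calibration inputs of the plant; everything else (ramp slopes, duty cycle,
time-to-setpoint, plateau stability) is recomputed. Passing checks
therefore demonstrate *round-trip consistency* of the model, controller and
analytics — they do not, and cannot, re-establish the in-vivo measurements
themselves, which encode biological variability (probe placement, perfusion,
tissue drying) that the lumped model does not represent.

## Plant model

Three compartments:

* **Target lobe** `T1`: `dT/dt = relay·h(T) − [T > T_chamber]·L0`, with
  gross on-rates `h_i` piecewise constant over contiguous temperature
  intervals and a constant loss rate `L0` active only above the chamber
  temperature. Cooling clamps at the chamber temperature.
* **Shielded body** `T2`: linear drift `body_drift ≤ 0` from a 37 °C
  baseline, clamped at the chamber temperature. The default
  `−0.03 °C/s` yields a ~2.5 °C decline over the ~85 s reference protocol,
  the "few degrees" scale of core cooling seen when the only heat source in
  the chamber is the water trap.
* **Water trap**: passive energy bookkeeping,
  `dT_water/dt = relay·P·f/(c_w·m)` with `c_w = 4.184 J/(g·°C)`,
  `m = 100 g`, and `f = 100/101` (the power split read as mass-proportional
  across ~100 g of water and ~1 g of lobe; configurable). It does not feed
  back on the lobe — the physical rig uses it purely as an energy sink.

**Constant-rate vs Newtonian loss.** A temperature-proportional loss would
make the plateau duty depend on the plateau temperature relative to
ambient; the constant-rate form instead gives the clean bang-bang identity
`duty = L0/h`, which is exactly consistent with calibrating `L0` from a
single printed duty figure and three printed slopes. Over the narrow
30–44 °C working range (10–24 °C above ambient) the two forms are barely
distinguishable; the Newtonian variant is out of scope.

**Interval-specific rates.** The decline of the net slope across intervals
(3.375 → 0.291 → 0.136 °C/s) is encoded phenomenologically as
interval-specific gross rates. Physically it may mix plant effects (tissue
drying, changing absorption) with controller effects (switching near the
margin); the rig does not resolve which dominates, and the controller-side
mechanism is additionally demonstrated by the noise–slope experiment below.

**Integration.** Explicit Euler at `sim_dt = 1 ms`. The scheme is *exact*
whenever the rate is constant across a step, which is the operating regime;
the only discretisation error is at interval breakpoints and relay
switches, bounded by one step. `predict_ramp_time` provides the closed-form
continuous-time ramp duration (`Σ span/(h_i − L0)`) as an independent
oracle; simulated first crossings agree within one step.

## Sensing

Per-sample model: `value = quantize(truth + N(0, σ) + Bernoulli(p)·A)`,
quantized to 0.01 °C (round half away from zero). Defaults: 10 kHz sampling
(the source material states both 10 kHz and 100 kHz; 10 kHz is the default
and both are configurable), `σ = 0.05 °C` for stochastic experiments and 0
for reference runs, spikes off (`p = 0`) because the physical rig
eliminated them by grounding — they exist to exercise the filter, with an
arbitrary 5 °C amplitude since the real artifacts were never quantified.
The protocol seed fans out via `SeedSequence.spawn` into four independent
per-channel streams (T1a, T1b, T2a, T2b), so runs are bit-reproducible.

## Controller

Moving average over 10 raw samples (exact summation, so the mean is
permutation-invariant and bounded by the buffer extremes), one relay
decision per full window (1 kHz at 10 kHz sampling), hysteresis band
`[setpoint − 0.1, setpoint]`. Band placement is a design choice: anchoring
the upper limit at the setpoint makes "reached the target" and "switch off"
the same event, which is how the dwell timer is specified to start. The
control signal is the mean of the two target-lobe channels; the unheated
control lobe cannot reach a setpoint, so it does not gate the dwell.
Relay switching is instantaneous (no magnetron warm-up lag is modelled).

Dwell duration per stage is not documented for the original instrument;
the reference protocol uses 20 s per stage, long enough for ≥ 10 relay
cycles at the 42 °C plateau and keeping the full protocol under 90 s
(the physical procedure kept total oven time below 3 minutes).

**Containment.** With noiseless sensing the filtered temperature stays, on
every settled dwell, within the hysteresis band widened by one control
period of heating *plus one quantization step*: the 0.01 °C sensor
resolution shifts the effective switching thresholds by up to half a step
each way (e.g. the relay re-arms at a reading of 41.89 rather than
41.8999…), so the ideal-band bound `[sp − 0.1 − h·Δt_c, sp + h·Δt_c]`
acquires a ± 0.01 °C margin. The numeric tests assert exactly that widened
bound.

## Runner and file formats

The loop advances the plant by 1 ms, emits 10 sensor samples per step
(zero-order hold), decides at the window cadence, and records a decimated
trace at 100 Hz (the raw 10 kHz stream is not persisted). Decision and
relay-transition timestamps live on the plant-step grid; consequently the
relay log can be reconstructed exactly from the trace's relay column only
when the record rate equals the decision rate (tested at 1 kHz recording),
and only approximately (± one record interval) from the default 100 Hz
trace. Simulated traces carry the plant's ground-truth lobe temperature as
an extra in-memory series for validation; it is not part of the CSV schema,
since a physical rig has no such channel.

Traces are CSV (`time_s,T1_raw,T1_filt,T2,relay`, 6 significant digits, LF,
UTF-8) with run metadata in a leading `# meta:` JSON comment; relay logs are
`time_s,state` transition lists (off before the first transition, last
state persisting). Malformed header, non-monotone time and non-numeric
cells raise distinct parse errors. Configs are TOML with
`[plant] [sensor] [controller] [protocol]` sections; the plant section
accepts either explicit `heat_rates` + `loss_rate` or the calibration form
(`net_slopes`, `duty`, `breakpoints`), and the packaged `reference.toml`
uses the calibration form. A 300 s simulated-time cap guarantees
termination, failing with the stage that stalled.

## Analysis

* **Segmentation** operates on the filtered channel. Segment `k` runs from
  the first row at/above breakpoint `k` after the last excursion below it,
  up to the first row at/above breakpoint `k+1` — i.e. the rising ramp,
  excluding the dwell plateau spent holding breakpoint `k`. On monotone
  traces this is the plain first-crossing half-open rule. Crossing
  detection uses a tolerance of one quantization step (0.01 °C) because a
  controller that switches off *at* the setpoint keeps its plateau a hair
  below it, and the millisecond peaks that do touch it fall between
  decimated rows. A breakpoint never reached yields an open, flagged
  segment, never a silent truncation.
* **OLS fits** via `scipy.stats.linregress`; `R² = 1 − SSR/SST`, defined as
  0 with a warning when the response has zero variance; slope p-values are
  reported but are not validation targets.
* **Duty cycle** integrates the relay step function over a window with
  clipped boundary intervals. The reference window runs from 2 s after the
  first setpoint crossing (settling) to the stage end; for randomized
  bang-bang checks the tests align the window on relay-on transitions so an
  integer number of cycles is measured and partial-cycle bias (up to one
  on-phase over the window) drops out.
* **Plateau stats**: mean, population SD, and the worst excursion beyond
  the hysteresis band.
* **Aggregation**: linear interpolation onto a common grid, mean and
  sample SD (n − 1).
* **Calibration**: `L0 = D·s_a/(1 − D)`, `h_i = s_i + L0`, anchored by
  default on the second interval (the one feeding the 42 °C reference
  plateau from below); the last interval's upper bound is opened to +∞ so
  millisecond overshoots above the final breakpoint stay covered.

## Bioheat solver

`−k∇²T = q` with Dirichlet walls, 5-point finite differences on a
node-centred grid, assembled sparse and solved by direct LU; the solution
is verified against a Jacobi-update residual at the requested tolerance.
`ny = 1` selects a 1-D slab (Dirichlet at the two x-walls only), for which
the quadratic closed forms (`T = T_wall + qx(L−x)/2k`, centre rise
`qL²/8k`) hold exactly at the nodes and serve as oracles. Deposition is
uniform or exponentially attenuated (`q0·e^{−x/δ}`) along x from the tissue
edge; `scale_to_core` exploits linearity to match a 40 °C core with a
single factor. Defaults: 2 × 2 cm slab at 0.2 mm spacing,
`k = 0.52 W/(m·°C)` (typical soft tissue — a configurable stand-in, since
the original simulation deferred material properties to tissue-property
databases without printing values), 20 °C walls. Perfusion and metabolic
terms are deliberately absent, and the grid is 2-D with the 0.5 cm
thickness treated as homogeneous: the claims tested are qualitative
homogeneity comparisons, not absolute dosimetry.

## Noise–slope experiment

The claim that narrow margins slow the approach (the relay "turning off"
on short-lived readings inside the margin) is tested as: the mean effective
ramp rate toward a 42 °C target is non-increasing in sensor noise SD over
{0, 0.1, 0.3} °C across 10 seeds. The effective rate is fitted on the
*ground-truth* temperature between its 40 °C and `setpoint − band`
crossings: noise-triggered relay drops can only delay true heating, whereas
estimating the slope from the noisy filtered channel lets early
threshold-detection truncate the slow chatter tail and mask the effect.
Below ~3 filtered-noise SDs of the margin the trajectories tie exactly with
the noiseless run, so equality at low noise is expected.

## Problem sizes

Reference protocol: ~85 simulated seconds (≈ 85 000 plant steps, 850 000
sensor samples), sub-second wall time. Randomized bang-bang checks: 40 s
dwells, five plant draws. Noise–slope experiment: 30 runs of ~20 s.
Bioheat grids: 101 × 101 (2-D) and 101/201-node slabs.
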