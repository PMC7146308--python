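# Methods

This note documents the models implemented in `wearhar`, their assumptions,
the defaults and why they were chosen, and what the synthetic data does and
does not establish.

## Signal model and synthetic data

No human recordings ship with the package. The generator
(`wearhar.synthetic`) emulates a wrist-worn dual-sensor device:

* accelerometer, 14 Hz, values in g;
* gyroscope, 17 Hz, values in deg/s (the two rates are deliberately
  unequal, as on the modelled hardware, which is why gyro alignment by
  repetition padding exists at all).

Per axis, acceleration is `gravity + A·sin(2πft + φ_axis) + ε`,
with fixed per-axis phases (0, 2π/3, 4π/3) and white Gaussian noise ε;
angular rate is a constant mean plus white noise. This is the simplest
model that reproduces the *discriminative structure* the pipeline relies
on, which is the only property the downstream stages need:

| band | activities | amplitude A (g) | what separates them |
|---|---|---|---|
| Sedentary | sitting, lying, standing | 0.01–0.02 | gravity orientation |
| Moderate | walking, turning L, turning R | 0.25–0.40 | walking by accel; L/R **only** by the sign of the mean X gyro rate (±40 deg/s) |
| Rigorous | jumping, running, exercising | 1.0–1.5 | accel amplitude/frequency |

Amplitudes are strictly ordered Sedentary < Moderate < Rigorous, so energy
bands are separable from accelerometer statistics alone; turning-left and
turning-right share every accelerometer parameter. Noise levels (0.02 g
sedentary, 0.05 g moderate, 0.10 g rigorous; 2–60 deg/s gyro) were fixed
once as plausible for consumer MEMS sensors at these activity intensities.

What the generator does **not** model: biomechanically realistic gait,
subject-to-subject variability, sensor drift and misalignment, transitions
within a window. Consequently, accuracies measured on synthetic data are
properties of this generator, not estimates of field performance; tests
assert structural facts (band separability, the gyro's role for turning
direction, gating soundness) rather than absolute accuracy levels beyond a
coarse ≥90% band-accuracy floor.

All generators are pure functions of (parameters, seed); a master seed fans
out to per-stage seeds via `numpy.random.SeedSequence`.

## Windowing

The processing window is the accelerometer's 32-sample FIFO with a
16-sample overlap (stride 16), so a window spans 32/14 ≈ 2.286 s and
windows start at sample indices 0, 16, 32, … A window's ground-truth label
is the majority of its per-sample labels, ties broken by earliest
occurrence (a deterministic rule chosen because some rule is needed; single-
activity traces are unaffected). Gyro samples are aligned to the half-open
accelerometer window span; fewer than 32 in-span samples are padded by
repeating the last, more are truncated to the earliest 32.

Byte accounting uses the converted 16-bit-per-axis representation
(32 × 3 × 2 = 192 bytes per window) even though acquisition is 12-bit,
because the on-device pipeline converts the FIFO to 16-bit integers before
processing. Feature math runs on continuous values; 12-bit/16-bit
quantization helpers exist for debugging and byte accounting only — where
quantization enters the arithmetic is a modelling choice, and keeping the
feature path continuous keeps every feature testable against closed-form
oracles.

## Features

Per axis and sensor: maximum, median, minimum, mean and **population**
variance (divide by n — the cheapest embedded form). Median of an
even-length window is the midpoint of the two central order statistics.
IMA is rectangular integration of the summed absolute triaxial components,
`dt · Σ_t (|ax|+|ay|+|az|)`, without gravity subtraction; normalization
conventions for IMA vary in the literature, and this form is the one whose
cost the energy table prices. Subsetting is first-class: only requested
features are computed, and the resulting mask is what the energy model
prices.

## Forests

Trees are CARTs grown **best-first by impurity decrease** with a hard cap
on internal nodes ("splits"): a cap of `s` splits gives at most `2s+1`
nodes and `s+1` leaves, which is the flash-budget arithmetic of an embedded
implementation. The cap is on node count, not depth — the node/edge/leaf
arithmetic only works under that reading. Individual trees are fitted with
scikit-learn (`max_leaf_nodes = max_splits + 1` implements exactly this
growth); each tree is then converted to a flat, JSON-serializable node list
on which all prediction runs, so train → serialize → load → predict is
bit-identical. Forest prediction is the arithmetic mean of the trees' leaf
class distributions.

Defaults for the reduced on-board models: 10 trees, 5 splits, Gini,
bootstrap with replacement (sample size = training-set size), minimum split
size 10, minimum leaf sizes 71/143/47/74 for Stage 1 / Sedentary /
Moderate / Rigorous. The leaf minima are absolute counts calibrated to the
full 9×1000-window training size; on smaller desk-scale fixtures they
simply stop growth earlier.

Feature importance is the total impurity decrease attributable to each
feature, normalized to sum to 1, ties broken lexicographically for
determinism. The reduction rule ranks features by importance and returns
the smallest prefix whose mean held-out accuracy is within 2 percentage
points of the full-set accuracy, capped at 8 features. Accuracy is
estimated over repeated random 50/50 class-balanced splits; the default is
100 repetitions, a desk-scale choice that keeps the estimate's noise well
below the 2-point tolerance.

## Hierarchy and gating

Stage 1 classifies the energy band from accelerometer features only (adding
gyro features to Stage 1 buys nothing by design of the task, and the gyro
may be off). The band selects the Stage-2 forest. The gyro gate is a
one-bit state threaded across windows, initially off:

* gate turns on exactly when Stage 1 says Moderate, off otherwise
  (symmetric deactivation minimizes energy);
* because gyro samples only exist from the next window onward, a window is
  classified with the accel+gyro Moderate model only if the *previous*
  window's decision was Moderate; the first Moderate window after any other
  band uses the accel-only Moderate model.

The accel+gyro Moderate model uses the Moderate accel subset plus
`gyr_mean_x` by default — the single gyro feature that resolves turning
direction.

Packet layout (4 bytes): byte 0 packs the band index in the high nibble and
the within-band class index in the low nibble; bytes 1–3 are the engaged
Stage-2 posterior quantized as `round(p·255)` (decoded error ≤ 1/510 per
component). The posterior transmitted is the Stage-2 one because its three
components match the three within-band classes.

## Energy and lifetime

`T = E_BAT / (P_I + P_A + P_G + P_MCU)`, reported in days for `E_BAT` in
joules and powers in μW. `P_MCU` is per-event energy times event rate:

* **raw streaming**: (single-sample SPI read(s) + radio-buffer copy + BLE
  advertisement) × 17 Hz;
* **on-board**: (`E_T` + Σ feature energies + Stage-1 + Stage-2 energies)
  × 0.87 Hz, with `E_T = E_FIFO_A/2 + E_FIFO_G/2 + E_BLE + E_DATA`; the
  FIFO-read terms are halved because one FIFO refill serves two overlapped
  classifications.

Stage-2 terms are weighted by band occupancy (defaults 0.808 / 0.188 /
0.004 — the fraction of the day an average person spends in each band).
Features shared with Stage 1 are priced once; branch-specific extras are
priced at their band's occupancy. In the gated configuration every
gyro-linked term (sensor power, gyro FIFO read, gyro features) is prorated
by the Moderate occupancy, which is the expected fraction of time the gate
is open under stationary band statistics.

Per-event energies default to bench measurements of the reference hardware
(e.g. 73.16 μJ per BLE advertisement, 8.14 μJ per IMA, 0.79–1.41 μJ per
classifier execution). The average powers `P_I`, `P_A`, `P_G` are **config
inputs**, not derivable from the event tables (they depend on sensor
duty-cycling internals outside this model); the shipped defaults
(3.3 / 3.0 / 3900 μW) are plausible figures for the modelled parts'
standby and gyro-active modes. Absolute power and lifetime outputs
therefore track the configured constants and should be read as model
outputs of the configured device, while the *accuracy* column of the
trade-off table is exact arithmetic. Notably, the printed per-advertisement
energy alone (73.16 μJ × 17 Hz ≈ 1.24 mW) makes raw streaming's MCU power
≈1.46 mW; raw-mode radio accounting cannot be pinned down more tightly
from per-event constants, which is why every constant is exposed in the
`EnergyTable` config rather than hard-wired.

The four reference operating points (`reference_operating_points()`) carry
the per-stage accuracies of the full off-board models and the reduced
on-board models on the 9-activity task as inputs; the cascade formula
`A = a_s1 · Σ w_i a_s2(i)` combines them. These four rows are what
`scripts/acceptance.py` recomputes.

## Numerical choices and degenerate inputs

* Population variance throughout; float arithmetic, no fixed-point
  emulation.
* Traversal convention `x ≤ threshold → left`, matching the fitted trees.
* Single-class training input yields a flagged degenerate single-leaf
  forest rather than an error; empty input raises.
* A trace shorter than 32 accelerometer samples yields zero windows, not an
  error.
* JSON serialization stores thresholds and leaf distributions as Python
  floats (repr round-trip), so reload is bit-exact.
* Posterior quantization uses banker's rounding via numpy; the 1/510 error
  bound holds either way.

## Problem sizes

Test fixtures train on 9 × 150 windows and evaluate on an independently
seeded 9 × 50-window set; the CLI `repro` default is 9 × 200. The
9 × 1000-window shape of the full study is exercised as arithmetic and
available by passing `windows_per_class=1000`. The reduction protocol's
100-split default applies throughout.

## Known limitations

* Synthetic signals are stationary sinusoids; no transitions inside a
  window, no postural drift, no per-subject variation — accuracy numbers on
  them say nothing quantitative about human data.
* The energy model is linear in event rates and energies; battery
  non-linearity and protocol-level radio behaviour beyond one advertisement
  per classification are out of scope.
* Mesh/gateway latency is not modelled; only the on-device sensing latency
  (FIFO fill, ≈2.3 s) is accounted.
* The trained-on-device C code path (emitting trees as C arrays) is out of
  scope; serialization targets JSON.
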