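# wearhar

Desk-scale simulation of **on-board activity classification for wearable
inertial sensors**: a hierarchy of tiny random forests that runs on the
device, duty-cycles the power-hungry gyroscope under classifier control, and
broadcasts 4-byte "knowledge" packets instead of raw data — together with
the power/lifetime model that quantifies what this buys.

## The problem

A wrist-worn health-monitoring device carries an ultra-low-power triaxial
accelerometer (14 Hz, ±8 g, 32-sample FIFO) and a gyroscope (17 Hz) that
draws orders of magnitude more power. Streaming raw samples over BLE costs
so much energy that batteries die in days and data is lost to poor
recharging compliance. The alternative simulated here classifies activities
*on the device*:

1. **Windowing** — the accelerometer FIFO yields 32-sample windows with
   16-sample overlap (one window fills in 32/14 ≈ 2.3 s).
2. **Features** — cheap time-domain statistics per axis (max, median, min,
   mean, population variance) plus the Integral of the Modulus of
   Acceleration (IMA): 16 accelerometer and 15 gyroscope features.
3. **Tier 1** — a reduced random forest assigns the window to an energy
   band: Sedentary, Moderate or Rigorous, from accelerometer features only.
4. **Tier 2** — a per-band forest recognises the activity (e.g. sitting /
   lying / standing within Sedentary). Only the Moderate band benefits from
   the gyroscope (telling turning-left from turning-right), so the gyro is
   powered **only after a Moderate decision**; since its samples arrive one
   window late, two Moderate models exist — accelerometer-only and
   accelerometer+gyro.
5. **Output** — each window is distilled into 4 bytes (band + class in one
   byte, the 3-class posterior quantized to 1/255 in three bytes): a 1:48
   compression of the 192-byte raw window.

The forests are *reduced* for embedded deployment: at most 8 features per
classifier (importance-ranked prefix, accepting at most a 2-percentage-point
accuracy loss versus the full set), 10 trees, at most 5 splits per tree
(11 nodes / 10 edges / 6 leaves), Gini impurity, bootstrap with replacement.

## The trade-off model

Device lifetime is

```
T = E_BAT / (P_I + P_A + P_G + P_MCU)
```

with battery budget `E_BAT` (default 1332 J), idle power `P_I`,
accelerometer/gyroscope average powers `P_A`, `P_G`, and MCU power `P_MCU`
assembled from per-event energies (μJ per SPI transfer, per feature, per
classifier execution, per BLE advertisement) times event rates — 17 Hz when
streaming raw samples, 0.87 Hz when classifying on board. How often each
Tier-2 classifier (and the gyro) runs is weighted by band occupancy
fractions `w = (0.808, 0.188, 0.004)` — the share of the day an average
person spends in each band. Overall accuracy of the cascade is

```
A = a_s1 * Σ_i w_i * a_s2(i)
```

Stage 1 gates everything, so its accuracy multiplies the occupancy-weighted
mean of the Stage-2 accuracies.

Because no human dataset ships with the package, a synthetic generator
reproduces the task's *discriminative structure* (bands separable from
accelerometer statistics; turning direction separable only through the mean
X-axis gyro rate) so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from wearhar import (default_activity_specs, generate_dataset, fit_hierarchy,
                     generate_trace, concat_traces, run_stream,
                     reference_operating_points, tradeoff_report)
from wearhar.synthetic import band_of

specs = default_activity_specs()
windows, labels = generate_dataset(specs, 100, seed=7)
model = fit_hierarchy(windows, labels, seed=11)
print(model.feature_subsets())

sp = {s.name: s for s in specs}
trace = concat_traces([generate_trace(sp["sitting"], 30, 1),
                       generate_trace(sp["turning_left"], 30, 2)])
packets, log = run_stream(model, trace)
print(len(packets), (log["band"] == log["true_label"].map(band_of)).mean())
print(tradeoff_report(reference_operating_points()).round(1).to_string(index=False))
```

prints

```
{'stage1': ['acc_var_x'], 'sedentary': ['acc_median_z'],
 'moderate_acc': ['acc_var_x'],
 'moderate_gyr': ['acc_var_x', 'gyr_mean_x'],
 'rigorous': ['acc_var_y', 'acc_var_x']}
51 1.0
        label  accuracy_pct  power_uw  lifetime_days
      RAW Acc          92.3    1462.7           10.5
RAW Acc + Gyr          96.3    5369.0            2.9
      EML Acc          86.7      94.6          163.0
EML Acc + Gyr          91.9     828.5           18.6
```

The reduction rule finds that, on the synthetic data, a single variance
feature separates the bands and the gyro mean-X feature resolves turning
direction. The 60-second stream cuts into 51 overlapping windows, all
assigned to the correct band. The trade-off table contrasts four operating
points — raw streaming vs on-board classification (EML), each with and
without the gyroscope: on-board classification trades a few accuracy points
for an order of magnitude in lifetime, and gating the gyro recovers most of
its accuracy benefit at a fraction of its always-on power cost.

A `wearhar` console script exposes the same workflow
(`simulate | train | classify | energy | repro`, see `wearhar --help`).

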