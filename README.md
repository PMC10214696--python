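# dualgait

Foot-worn inertial-sensor gait analysis and dual-task cognitive-status
assessment.

Subtle cognitive decline in older adults shows up in how walking degrades
when a cognitive task (counting backward by sevens) is added.  `dualgait`
implements the full measurement and analysis chain for such studies with
shoe-mounted IMUs (tri-axial accelerometer + gyroscope, 100 Hz, one sensor
per foot, arbitrary mounting), for researchers in human movement science
and digital biomarkers:

* a **synthetic-data generator** producing foot-IMU signals and two-group
  cohorts (control vs cognitively impaired) with known ground truth;
* a **ZUPT-anchored strapdown pipeline**: zero-velocity detection from
  angular-rate energy, complementary-filter orientation, direct+reverse
  gravity-removed integration, gait-event detection from low-pass-filtered
  acceleration, and 13 per-stride spatiotemporal metrics plus heel/toe
  trajectories — all invariant to the sensor's mounting orientation;
* **dual-task measures** per subject × condition:

  ```
  CV [%]  = 100 · SD / mean                      stride-to-stride variability
  SI [%]  = 100 · |L − R| / (0.5 · (L + R))      left/right asymmetry
  DTE [%] = 100 · (dual − single) / single       dual-task effect
  MAD     = (1/n) Σᵢ |xᵢ − x̄ᵢ|                   trajectory variability (mm)
  ```

  where `x̄ᵢ` is the cross-stride mean of the time-normalised trajectory at
  grid point `i`;
* **cohort statistics**: MoCA-based stratification (cutoff < 24, +1 point
  for ≤ 12 education years), a normality/outlier/variance decision tree
  selecting Student/Welch/Mann-Whitney and paired-t/Wilcoxon tests,
  logistic-regression ROC discrimination with Hanley-McNeil SE and the
  closest-to-(0,1) optimal cut-point, and bivariate plus stepwise-forward
  regressions of MoCA on gait metrics.

## Worked example

```python
from dualgait import simulate_walk, extract_strides, CONTROL_PROFILE
from dualgait.workflow import summarize_recordings, strides_to_frame

recs, truth = simulate_walk(CONTROL_PROFILE, "single", n_strides=12, seed=1)
records = extract_strides(recs["left"])
print(strides_to_frame(records)[["stride_time", "stride_length", "gait_speed",
                                 "strike_angle", "min_toe_clearance"]].round(3))

summary, _ = summarize_recordings(recs["left"], recs["right"])
print("mean gait speed [m/s]:", round(summary.mean["gait_speed"], 3))
print("stride-time CV [%]:  ", round(summary.cv["stride_time"], 2))
print("stride-length SI [%]:", round(summary.si["stride_length"], 2))
print("heel forward MAD [mm]:", round(summary.mad["heel_forward"], 1))
```

prints the 8 retained strides (a 12-stride pass minus the first/last two,
minus the warm-up segment) of a simulated control subject:

```
 stride_time  stride_length  gait_speed  strike_angle  min_toe_clearance
       1.248          1.133       0.908       -19.073              0.996
       1.179          1.234       1.046       -25.045              1.036
       1.113          1.169       1.050       -25.378              3.476
       ...
mean gait speed [m/s]: 1.003
stride-time CV [%]:   4.3
stride-length SI [%]: 3.65
heel forward MAD [mm]: 29.3
```

Stride times ~1.2 s, lengths ~1.2 m, strike angles ~−20° and toe
clearances of 1–3 cm are typical of mobility-limited older adults; the
4.3% stride-time variability and ~29 mm forward trajectory MAD sit in the
expected single-task range for this population.

## Command line

```sh
dualgait simulate --seed 1 --out data/            # IMU text files + ground truth
dualgait extract  --in data/ --out derived/       # stride + cohort tables
dualgait analyze  --in derived/cohort_table.csv --out report.json
```

`simulate` writes per-recording 7-column text files (time, accel xyz,
gyro xyz), a metadata CSV and a ground-truth stride table; `extract`
reconstructs per-stride metrics and the wide per-subject cohort table;
`analyze` writes the group-comparison / ROC / regression report as JSON.
Every threshold of the pipeline lives in a single YAML config
(`--config`); all randomness flows from `--seed`.

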