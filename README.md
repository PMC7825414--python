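# backload

Wearable-sensor estimation of low-back loading during manual material
handling.

Occupational low-back injury risk is usually assessed from the **lumbar
extension moment** — the net internal moment at the L5/S1 joint resisting
forward trunk flexion — which labs obtain from optical motion capture and
force plates via bottom-up inverse dynamics.  `backload` is a tested,
reusable pipeline for the wearable version of that measurement: estimate
the time-series L5/S1 moment (extension, and optionally lateral bending)
from signals that body-worn sensors can provide — IMU orientations on up to
five body locations and pressure-insole normal force and center of
pressure — and quantify which sensor locations matter.

Because raw lab datasets of this kind are not public, the package includes
a first-class synthetic-data generator: a nine-segment rigid-body model
performing pick-and-place tasks (boxes of 0–23 kg, three shelf heights,
squat/stoop/lateral/diagonal styles), with minimum-jerk kinematics and
ground reaction forces synthesized so that every trial is dynamically
consistent to machine precision.  Ground truth comes from a recursive
Newton–Euler pass from the feet upward; an independent top-down recursion
over the trunk and handheld load serves as a numerical oracle.

The estimator is a histogram-binned gradient-boosted tree ensemble
(~100 trees) mapping the per-sample, z-scored wearable channels to the
moment in body weight × body height (BW×BH) units, evaluated under
leave-one-subject-out cross-validation:

- r² = 1 − SS_res/SS_tot per held-out participant, averaged;
- RMSE in BW×BH, converted to N·m with cohort-mean body weight and height;
- MAPE over samples whose true moment exceeds 0.05 BW×BH;
- permutation importance (Δr² when a channel is shuffled within its fold);
- an exhaustive sweep of all 62 reduced sensor-location subsets plus the
  full distributed set.

## Worked example

```python
from backload import (sample_cohort, build_task_battery, BatteryConfig,
                      simulate_trial, assemble_dataset, subset_features,
                      loso_cv)
from backload.evaluate import accuracy_report

cohort = sample_cohort(6, seed=0)
battery = build_task_battery(
    BatteryConfig(box_masses=(5.0, 10.0, 15.0, 23.0),
                  shelf_pairs=(("low", "mid"), ("mid", "high")),
                  styles=("squat", "stoop", "lateral", "diagonal"),
                  repetitions=1),
    seed=0)
trials = [simulate_trial(a, task, seed=k)
          for a in cohort for k, task in enumerate(battery)]

features, target = assemble_dataset(trials, provenance="idealized", stride=4)
for locations in (("trunk",), ("insole",), ("trunk", "insole")):
    cv = loso_cv(subset_features(features, locations), target)
    report = accuracy_report(cv, cohort)
    print(f"{'+'.join(locations):13s} r2={report.r2_mean:.3f}  "
          f"rmse={report.rmse_nm:.1f} Nm  mape={report.mape_pct:.0f}%")
```

prints

```
trunk         r2=0.818  rmse=25.9 Nm  mape=23%
insole        r2=0.259  rmse=47.3 Nm  mape=36%
trunk+insole  r2=0.858  rmse=24.4 Nm  mape=17%
```

A trunk IMU alone tracks posture-driven loading well (r² 0.82) but cannot
see how heavy the handheld box is; pressure insoles alone see the load but
not the posture (r² 0.26); fusing the two recovers both (r² 0.86, and the
MAPE on the high-moment samples — the ones that matter for injury risk —
drops from 23 % to 17 %).  At the full study scale (10 participants × 100
tasks) the same orderings hold with larger margins, and every single
held-out participant improves when insoles are added.

## Command-line runner

Whole experiments are driven by a YAML config:

```yaml
# study.yaml
seed: 7
cohort: {n: 10}
battery: {repetitions: 1}
features: {provenance: idealized, stride: 4}
target: extension          # or lateral_bending
sweep: {subsets: all, stride: 8}
```

```bash
backload all study.yaml --out runs/study   # or: generate/features/train/sweep/evaluate/report
```

Stages are cached by config hash, so re-running an unchanged config is
free, and each stage can be invoked separately.  The run directory holds
cohort and battery manifests (CSV), the feature matrix and targets (npz +
parquet + channel-metadata JSON), per-subset CV metrics (JSON), the sweep
table (CSV + markdown), importance table (CSV), and a rendered `report.md`
with figures.  Individual trials can be exported/ingested as wide CSV or
Parquet time-series files with a JSON sidecar (see
`backload.trialio` for the column contract).

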