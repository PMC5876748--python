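# gaitphase

Four-phase gait partitioning from foot-worn inertial sensors, with the
evaluation and gait-quality machinery used to compare partitioning methods
in Parkinson's disease research.

## The problem

Wearable gait analysis splits every gait cycle (heel strike to heel
strike) into four phases:

| Phase | From | To |
|---|---|---|
| Loading Response (LR) | heel strike (HS) | toe strike (TS) |
| Flat Foot (FF) | toe strike | heel off (HO) |
| Pre-Swing (PS) | heel off | toe off (TO) |
| Swing (Sw) | toe off | next heel strike |

The distribution of time over these phases is clinically meaningful in
Parkinson's disease: shuffling, hobbling gait inflates flat foot and
shortens swing, and the distribution shifts with levodopa state. This
package implements the full desk workflow for studying that signal:

- **Reference labeling** from four footswitches per foot (heel, 1st and
  5th metatarsophalangeal, toe): LR = only heel pressed, FF = all pressed,
  PS = at least one forefoot switch pressed, Sw = none pressed.
- **Two threshold segmenters** over the IMU streams: the *S-method*
  (sagittal angular velocity, 30 °/s stasis threshold, trough-based HS/TO)
  and the *R-method* (filtered acceleration resultant c50, its
  derivatives, and two moving-average constraint bands cA200/cA50).
- **Two scalar continuous-HMM segmenters**: a 4-state left-right cyclic
  hidden Markov model with Gaussian-mixture emissions over the low-pass
  filtered sagittal angular velocity, trained by Baum-Welch and decoded by
  Viterbi — either *subject-specific* (train on 2 of a subject's 3
  trials, decode the third) or with a *standard training set* (pool a
  control group once, decode anyone).
- **Evaluation**: transition-level TP/TN/FP/FN inside a 60 ms centred
  tolerance window, sensitivity TPR = TP/(TP+FN), specificity
  TNR = TN/(TN+FP), and the Goodness index

  ```
  G = sqrt((1 - TNR)^2 + (1 - TPR)^2)
  ```

  (distance to the perfect ROC corner; ≤ 0.25 optimum, ≤ 0.7 good,
  otherwise random), plus per-phase absolute percentage errors and
  rank-sum ROC/AUC utilities.
- **Gait Phases Quality Index (GPQI)**: for each side *i*, the Euclidean
  distance between the subject's phase-percentage vector and healthy
  control-group means, summed over sides:

  ```
  GPQI = Σᵢ sqrt((LRᵢ-mLR)² + (FFᵢ-mFF)² + (PSᵢ-mPS)² + (Swᵢ-mSw)²)
  ```

  with test-retest reliability via ICC(3,k), SEM and MDC95.
- **A seeded synthetic gait generator** producing per-foot IMU (50 Hz) and
  footswitch (2000 Hz) streams with exact ground-truth events, in healthy
  and parkinsonian-like presets, so the whole stack is testable end to end
  without patient data.

Segmenters follow scikit-learn conventions (`fit`/`predict`,
`get_params`/`set_params`, fitted attributes with trailing underscores).

## Worked example

```python
import numpy as np
from gaitphase import preset, generate_trial, label_phases, segment_strides
from gaitphase import SMethodSegmenter, train_spt, gpqi, control_reference
from gaitphase.pipeline import make_cohort, make_trial, score_sequence
from gaitphase.reference import mean_percentages

profile = preset("healthy", seed=42)
imu, fsw, truth = generate_trial(profile, n_strides=20)
reference = label_phases(fsw)
strides = segment_strides(reference)       # discards 3 strides at each end
print("retained strides:", len(strides))
print("mean phase percentages:", np.round(mean_percentages(strides), 1))

trial = make_trial(imu, fsw, truth)
pred = SMethodSegmenter().fit().predict(imu)
res = score_sequence(trial, pred)
print(f"S-method: TPR={res.TPR:.3f}  TNR={res.TNR:.3f}  "
      f"G={res.G:.3f} ({res.performance_class})")

cohort = make_cohort(profile, n_trials=6, n_strides=20, seed=0)
spt = train_spt([(t.imu, t.reference) for t in cohort[:5]], max_iter=25)
res = score_sequence(cohort[5], spt.predict(cohort[5].imu))
print(f"HMM (standard training): G={res.G:.3f} ({res.performance_class})")
```

prints

```
retained strides: 14
mean phase percentages: [ 7.  39.3 16.  37.8]
S-method: TPR=0.982  TNR=1.000  G=0.018 (optimum)
HMM (standard training): G=0.018 (optimum)
```

The 20-stride trial keeps 14 strides after discarding the accelerating
and decelerating cycles; the recovered phase distribution matches the
healthy profile (6.9, 39.4, 16.2, 37.7)% up to stride-to-stride jitter;
both segmenters land in the optimum band (G ≤ 0.25) against the
footswitch reference.

A command-line interface mirrors the stages:

```bash
gaitphase simulate --preset pd_severe --n-strides 20 --seed 1 --out trial/
gaitphase label-reference trial/footswitch.csv --out ref.json --strides-out strides.csv
gaitphase segment trial/imu.csv --method s --out pred.json
gaitphase evaluate ref.json pred.json --out metrics.json
gaitphase pipeline --seed 1 --out report/   # full methods x presets table
```

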