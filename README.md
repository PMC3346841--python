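# fallsense

Fall detection and fall-type classification from mobile-phone
accelerometry, as a reproducible Python pipeline.

Falls are a leading source of injury in the elderly, and phones carried on
a belt already contain the sensor needed to catch them: a tri-axial
accelerometer reporting specific force (≈9.8 m/s² on the up-axis at rest)
at a variable 15–25 Hz. `fallsense` implements the full analysis chain for
two tasks on such recordings:

1. **classification** — given a fall, which of four directional classes was
   it (backward slip, forward trip, left or right lateral fall)?
2. **detection** — is a high-impact event an actual fall, or one of the
   "fall-like" events of everyday life (jolts, hard sit-downs, walking
   impacts)?

Rather than hand-picking thresholds, the pipeline computes a large bank of
178 time-series features per 10 s clip — per-axis moments and
difference moments, smoothed RMS, extremes, z-score histogram counts,
sampled Fourier magnitudes |X(f)| at 32 frequencies in [0, 10 Hz], mean
magnitude ‖a‖, and cross products — and lets regularized classifiers weigh
them: an RBF-kernel SVM (hyperparameters C, γ), sparse multinomial
logistic regression (L1 penalty λ, an embedded feature selector), naive
Bayes, a decision tree and k-nearest neighbours. Accuracy is estimated by
pooled stratified 10-fold crossvalidation and by leave-one-subject-out
("subject-wise") crossvalidation, the harder test of generalizing to an
unseen wearer. Negative examples for detection are mined from daily-wear
streams by a jerk statistic — the summed squared sample-to-sample change in
acceleration, smoothed over 2 s — keeping the single highest-scoring event
per recorded hour.

Since no human-subject recordings ship with the package, a synthetic-data
module generates both data sets with the study's structure: falls as a
stance → freefall → directional impact → lying phase sequence (18 trials
per subject, six raw types merged to four classes), and day-long wear
streams with walking, posture transitions and high-jerk non-fall events.
See `docs/methods.md` for the model and every numerical convention.

## Worked example

```python
from fallsense.classification import ClassifierSpec
from fallsense.experiments import (ExperimentConfig, report,
                                   run_classification_experiment)

cfg = ExperimentConfig(
    task="classification", n_subjects=5, seed=2, grid=True,
    specs=tuple(ClassifierSpec(f) for f in
                ("svm-rbf", "smlr", "naive-bayes", "decision-tree", "knn")),
    schemes=("kfold-10", "subject-wise"))
table, results = run_classification_experiment(cfg)
print(report(results).round(3).to_string())
```

prints (90 fall clips from 5 synthetic subjects):

```
               kfold-10  subject-wise  best_kfold-10  best_subject-wise
classifier
decision-tree     0.989         0.989          False              False
knn               1.000         1.000           True               True
naive-bayes       1.000         1.000           True               True
smlr              1.000         1.000           True               True
svm-rbf           1.000         1.000           True               True
```

Each cell is the proportion of 10 s fall clips whose class (slip, trip,
lateral-left, lateral-right) was predicted correctly under that
crossvalidation scheme; `best_*` flags every classifier tied for the
column maximum. At this desk scale most families are at ceiling — the
differences between them emerge at the full study size (see
`examples/detect_falls.py` and the acceptance script). The
`examples/` directory holds one short script per capability: simulating
falls, mining fall-like events, featurizing a clip, and running both
experiments.

A thin CLI wraps the same library calls:

```bash
fallsense simulate --subjects 15 --wear-subjects 9 --wear-hours 24 --seed 1 --out study/
fallsense extract-events --in study/wear/S01.csv --out events.csv
fallsense featurize --in study/falls --out features.csv
fallsense evaluate --config cfg.yaml
```

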