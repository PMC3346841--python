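"""Fall detection: simulated falls vs mined fall-like events.

A small detection study — 4 fall subjects, 2 wear subjects x 3 h — where
the negative class is not random data but the most fall-like (highest-jerk)
event of each recorded hour, mirroring how hard negatives are collected
from daily life.
"""

from fallsense.classification import ClassifierSpec
from fallsense.experiments import (ExperimentConfig, report,
                                   run_detection_experiment)

cfg = ExperimentConfig(
    task="detection", n_subjects=4, n_wear_subjects=3, wear_hours=6.0, seed=6,
    specs=(ClassifierSpec("svm-rbf"), ClassifierSpec("naive-bayes")),
    grid=True, schemes=("kfold-10",))
table, results = run_detection_experiment(cfg)

n_fall = (table["label"] == "fall").sum()
n_neg = (table["label"] == "non-fall").sum()
print(f"{n_fall} fall clips vs {n_neg} mined fall-like clips\n")
for (family, scheme), res in results.items():
    print(f"{family:12s} {scheme}: accuracy {res.accuracy:.3f}")
    print("  confusion matrix (rows true, cols predicted, order "
          f"{res.labels}):\n  {res.confusion_matrix.tolist()}")
print("\nOff-diagonal counts are missed falls (top-right) and false alarms"
      "\n(bottom-left).  At this desk scale the negative class is tiny, so"
      "\naccuracies are noisy; the full-scale study (15 fall subjects, 9 wear"
      "\nsubjects x 24 h) is where SVM/SMLR pull clear of naive Bayes.")
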