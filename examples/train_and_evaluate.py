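"""Subject-wise nested cross-validation on a synthetic cohort.

The outer 3-fold split is stratified on the label powerset and grouped by
subject (no child in both train and test); the inner loop tunes
hyperparameters by successive halving on the outer-training data only.
Afterwards the per-fold winners are averaged into one deployment model.
Runs at desk scale in about a minute.
"""

import mannerkit as mk
from mannerkit.evaluation import desk_space, printed
from mannerkit.model import desk_config

cohort = mk.simulate_cohort(
    mk.default_cohort(n_subjects=8, seed=0, dropout_prob=0.0))
windows = mk.windows_from_sim(cohort)
balanced = mk.select_and_balance(windows, seed=0)
print(f"balanced dataset: {len(balanced)} windows from 8 subjects")

result = mk.nested_cv(
    balanced, k=3, mode="subject_wise", seed=0,
    base_config=desk_config(seed=0), space=desk_space(), budget=2,
)
for fold in result.folds:
    print(f"fold {fold.fold}: test subjects {fold.test_subjects}, "
          f"macro accuracy {fold.report.macro.accuracy:.3f}, "
          f"macro F1 {fold.report.macro.f1:.3f}")

summary = result.summary()["macro"]
print("macro accuracy mean (min-max): "
      f"{summary['accuracy']['mean']:.3f} "
      f"({summary['accuracy']['min']:.3f}-{summary['accuracy']['max']:.3f})")

hp = mk.mean_hyperparameters([f.best for f in result.folds])
net, report = mk.train_deployment(balanced, hp, desk_config(seed=0), seed=0)
print(f"deployment hyperparameters: {hp}")
print(f"deployment held-in macro metrics: {printed(report.macro)}")
# Held-in metrics overstate generalization; the fold metrics above are the
# unseen-subject estimate.
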