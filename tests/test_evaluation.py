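"""Metric formulas, macro averaging, splitting, tuning, and nested CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mannerkit as mk
from mannerkit.errors import ValidationError
from mannerkit.evaluation import (
    ConfusionCounts,
    MetricBlock,
    SearchSpace,
    desk_space,
    round3,
    tune,
)
from mannerkit.model import desk_config

from conftest import make_window


class TestConfusion:
    def test_all_correct(self):
        lv = [mk.LabelVector(1, 0), mk.LabelVector(0, 1)]
        c = mk.confusion(lv, lv, "flapping")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_enumerated_pairs(self):
        truths = [(1, 0), (1, 0), (0, 0), (0, 0)]
        preds = [(1, 0), (0, 0), (1, 0), (0, 0)]
        c = mk.confusion(preds, truths, "flapping")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_empty_input(self):
        c = mk.confusion([], [], "jumping")
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            mk.confusion([(1, 0)], [], "flapping")

    def test_sklearn_cross_check(self):
        from sklearn.metrics import confusion_matrix
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c = mk.confusion(np.stack([p, p], 1), np.stack([t, t], 1), "flapping")
        tn, fp, fn, tp = confusion_matrix(t, p).ravel()
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestMetrics:
    def test_worked_example(self):
        m = mk.metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=6))
        assert m.accuracy == pytest.approx(0.8)
        assert m.recall == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(6 / 7)
        assert m.precision == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        m = mk.metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_zero_over_zero_conventions(self):
        m = mk.metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert m.recall == 0.0
        assert m.precision == 0.0  # 0/0 rule
        assert m.f1 == 0.0
        assert m.accuracy == 0.5

    def test_no_windows_rejected(self):
        with pytest.raises(ValidationError):
            mk.metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_f1_is_harmonic_mean_when_defined(self, tp, fp, fn, tn):
        if tp + tn + fp + fn == 0:
            return
        m = mk.metrics(ConfusionCounts(tp, fp, fn, tn))
        if tp + fp > 0 and tp + fn > 0 and m.precision + m.recall > 0:
            harm = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert m.f1 == pytest.approx(harm)
        for v in m.as_dict().values():
            assert 0.0 <= v <= 1.0

    def test_sklearn_cross_check(self):
        from sklearn.metrics import f1_score, precision_score, recall_score
        rng = np.random.default_rng(1)
        t = rng.integers(0, 2, 80)
        p = rng.integers(0, 2, 80)
        m = mk.metrics(mk.confusion(
            np.stack([p, p], 1), np.stack([t, t], 1), "flapping"))
        assert m.recall == pytest.approx(recall_score(t, p))
        assert m.precision == pytest.approx(precision_score(t, p))
        assert m.f1 == pytest.approx(f1_score(t, p))


class TestMacroAverage:
    def test_published_per_label_values_reproduce_macro_row(self):
        flapping = MetricBlock(accuracy=0.647, recall=0.390, specificity=0.843,
                               precision=0.647, f1=0.485)
        jumping = MetricBlock(accuracy=0.758, recall=0.101, specificity=0.932,
                              precision=0.307, f1=0.151)
        macro = mk.printed(mk.macro_average(flapping, jumping))
        assert macro == {"accuracy": 0.702, "recall": 0.245,
                         "specificity": 0.887, "precision": 0.477, "f1": 0.318}

    def test_identical_blocks_average_to_themselves(self):
        b = MetricBlock(0.5, 0.4, 0.6, 0.7, 0.3)
        assert mk.macro_average(b, b) == b

    def test_round3_resolves_ties_downward(self):
        assert round3(0.7025) == 0.702
        assert round3(0.2455) == 0.245
        assert round3(0.8875) == 0.887
        assert round3(0.3184) == 0.318


class TestMeanHyperparameters:
    def test_published_fold_table(self):
        folds = [
            mk.HyperparameterSet(256, 512, 384, 0.10, 32),
            mk.HyperparameterSet(256, 384, 512, 0.10, 16),
            mk.HyperparameterSet(128, 384, 512, 0.05, 32),
        ]
        m = mk.mean_hyperparameters(folds)
        assert (m.units_layer_1, m.units_layer_2, m.units_layer_3) == (213, 427, 469)
        assert m.dropout_rate == 0.083
        assert m.batch_size == 27

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            mk.mean_hyperparameters([])


class TestStratifiedGroupKFold:
    def build(self, n_subjects, per_subject=8):
        windows = []
        labels = [(0, 0), (1, 0), (0, 1), (1, 1)]
        for s in range(n_subjects):
            for i in range(per_subject):
                windows.append(make_window(
                    subject=f"s{s:02d}", start=i * 15,
                    label=labels[i % 4],
                ))
        return windows

    def test_three_subjects_three_folds(self):
        windows = self.build(3)
        folds = mk.stratified_group_kfold(windows, k=3, seed=0)
        for _, test in folds:
            assert len({windows[i].subject_id for i in test}) == 1

    def test_subjects_never_split(self):
        windows = self.build(7)
        folds = mk.stratified_group_kfold(windows, k=3, seed=1)
        for train, test in folds:
            tr = {windows[i].subject_id for i in train}
            te = {windows[i].subject_id for i in test}
            assert not tr & te

    def test_every_window_in_exactly_one_test_fold(self):
        windows = self.build(6)
        folds = mk.stratified_group_kfold(windows, k=3, seed=2)
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(len(windows)))

    def test_strata_balanced_for_identical_subjects(self):
        windows = self.build(6)
        folds = mk.stratified_group_kfold(windows, k=3, seed=3)
        for _, test in folds:
            classes = [windows[i].label.powerset_class for i in test]
            counts = np.bincount(classes, minlength=4)
            assert counts.max() - counts.min() <= 2  # one group's contribution

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            mk.stratified_group_kfold(self.build(2), k=3, seed=0)

    def test_random_mode_ignores_subjects(self):
        windows = self.build(3)
        folds = mk.stratified_group_kfold(windows, k=3, mode="random", seed=0)
        mixed = any(
            len({windows[i].subject_id for i in test}) > 1 for _, test in folds
        )
        assert mixed

    def test_deterministic_given_seed(self):
        windows = self.build(6)
        a = mk.stratified_group_kfold(windows, k=3, seed=5)
        b = mk.stratified_group_kfold(windows, k=3, seed=5)
        for (ta, ea), (tb, eb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(ea, eb)


class TestTune:
    def test_single_configuration_budget(self, small_windows):
        bal = mk.select_and_balance(small_windows, seed=0)
        space = SearchSpace(units=(8,), dropout_rates=(0.0,), batch_sizes=(16,))
        best, log = tune(bal, space, budget=1, seed=0,
                         base_config=desk_config(seed=0, epochs=3))
        assert best == mk.HyperparameterSet(8, 8, 8, 0.0, 16)

    def test_winner_has_best_final_round_score(self, small_windows):
        bal = mk.select_and_balance(small_windows, seed=0)
        best, log = tune(bal, desk_space(), budget=3, seed=1,
                         base_config=desk_config(seed=1, epochs=9))
        final_epochs = max(row["epochs"] for row in log)
        final = [row for row in log if row["epochs"] == final_epochs]
        winner_score = max(row["score"] for row in final if row["hp"] == best)
        assert all(winner_score >= row["score"] for row in final)

    def test_deterministic_winner(self, small_windows):
        bal = mk.select_and_balance(small_windows, seed=0)
        a, _ = tune(bal, desk_space(), budget=2, seed=3,
                    base_config=desk_config(seed=3, epochs=3))
        b, _ = tune(bal, desk_space(), budget=2, seed=3,
                    base_config=desk_config(seed=3, epochs=3))
        assert a == b

    def test_empty_training_data_rejected(self):
        with pytest.raises(ValidationError):
            tune([], desk_space(), budget=1, seed=0,
                 base_config=desk_config())


@pytest.fixture(scope="module")
def cv_result(small_windows):
    bal = mk.select_and_balance(small_windows, seed=0)
    return mk.nested_cv(
        bal, k=3, mode="subject_wise", seed=0,
        base_config=desk_config(seed=0, epochs=10),
        space=SearchSpace(units=(16,), dropout_rates=(0.0,),
                          batch_sizes=(16,)),
        budget=1,
    )


class TestNestedCV:
    def test_has_k_folds(self, cv_result):
        assert len(cv_result.folds) == 3

    def test_subjects_partition_across_test_folds(self, cv_result):
        seen = []
        for f in cv_result.folds:
            assert not set(f.train_subjects) & set(f.test_subjects)
            seen.extend(f.test_subjects)
        assert len(seen) == len(set(seen)) == 4

    def test_summary_shape(self, cv_result):
        s = cv_result.summary()
        for block in ("flapping", "jumping", "macro"):
            for metric in ("accuracy", "recall", "specificity", "precision", "f1"):
                stats = s[block][metric]
                assert stats["min"] <= stats["mean"] <= stats["max"]

    def test_deployment_model_consistent_with_cv(self, cv_result, small_windows):
        bal = mk.select_and_balance(small_windows, seed=0)
        hp = mk.mean_hyperparameters([f.best for f in cv_result.folds])
        net, report = mk.train_deployment(
            bal, hp, desk_config(seed=0, epochs=10), seed=0)
        # held-in performance should at least reach the CV mean
        cv_mean = cv_result.summary()["macro"]["accuracy"]["mean"]
        assert report.macro.accuracy >= cv_mean - 0.1


def test_random_split_is_not_pessimistic_vs_subject_wise(small_windows):
    """Letting a child's windows leak between train and test can only help:
    random-split macro accuracy should be >= the subject-wise estimate
    (within noise) on the same data, the direction of the optimistic bias."""
    bal = mk.select_and_balance(small_windows, seed=0)
    space = SearchSpace(units=(16,), dropout_rates=(0.0,), batch_sizes=(16,))
    accs = {"subject_wise": [], "random": []}
    for seed in range(2):
        for mode in accs:
            res = mk.nested_cv(
                bal, k=3, mode=mode, seed=seed,
                base_config=desk_config(seed=seed, epochs=10),
                space=space, budget=1,
            )
            accs[mode].append(res.summary()["macro"]["accuracy"]["mean"])
    diff = np.mean(accs["random"]) - np.mean(accs["subject_wise"])
    assert diff >= -0.05
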