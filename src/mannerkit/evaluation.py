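"""Nested subject-wise cross-validation, tuning, and per-label metrics.

Evaluation follows the clinical framing: the classifier must work on
children it has never seen, so the outer cross-validation splits by
subject (no child contributes windows to both train and test of a fold)
while stratifying on the label powerset {none, flapping, jumping, both}.
The inner loop tunes hyperparameters by budgeted successive halving using
only the outer-training data; the fold winner retrains on the whole outer
training set and is scored on the untouched outer test set. A random
(non-grouped) split mode is kept for the optimistic-bias comparison, and
the deployment rule averages the per-fold best hyperparameters for one
final model trained on everything.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .annotations import LabelVector
from .errors import ValidationError
from .features import Window, windows_to_arrays
from .model import LSTMNetwork, NetworkConfig, train

log = logging.getLogger(__name__)

LABEL_NAMES = ("flapping", "jumping")
METRIC_NAMES = ("accuracy", "recall", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label binary confusion counts; P = TP + FN, N = TN + FP."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class MetricBlock:
    """Accuracy, recall (sensitivity), specificity, precision, F1."""

    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class MetricsReport:
    """Per-label metric blocks plus their unweighted macro average."""

    flapping: MetricBlock
    jumping: MetricBlock
    macro: MetricBlock

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            "flapping": self.flapping.as_dict(),
            "jumping": self.jumping.as_dict(),
            "macro": self.macro.as_dict(),
        }


@dataclass(frozen=True)
class HyperparameterSet:
    """The tuned knobs: LSTM layer sizes, dropout rate, batch size."""

    units_layer_1: int
    units_layer_2: int
    units_layer_3: int
    dropout_rate: float
    batch_size: int

    def apply(self, base: NetworkConfig) -> NetworkConfig:
        from dataclasses import replace
        return replace(
            base,
            units=(self.units_layer_1, self.units_layer_2, self.units_layer_3),
            dropout_rate=self.dropout_rate,
            batch_size=self.batch_size,
        )


@dataclass(frozen=True)
class SearchSpace:
    """Discrete hyperparameter grid sampled by the tuner."""

    units: tuple[int, ...] = (128, 256, 384, 512)
    dropout_rates: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15)
    batch_sizes: tuple[int, ...] = (16, 32)

    def all_configurations(self) -> list[HyperparameterSet]:
        return [
            HyperparameterSet(u1, u2, u3, d, b)
            for u1, u2, u3, d, b in itertools.product(
                self.units, self.units, self.units,
                self.dropout_rates, self.batch_sizes,
            )
        ]


def desk_space() -> SearchSpace:
    """Reduced grid for desk-scale runs: fixed 32-unit layers."""
    return SearchSpace(units=(32,), dropout_rates=(0.0, 0.1), batch_sizes=(16, 32))


@dataclass
class FoldResult:
    fold: int
    best: HyperparameterSet
    report: MetricsReport
    train_subjects: list[str]
    test_subjects: list[str]


@dataclass
class CVResult:
    """Per-fold tuning winners and test metrics plus a summary."""

    mode: str
    folds: list[FoldResult]

    def summary(self) -> dict[str, dict[str, dict[str, float]]]:
        """Per block and metric: mean, min, max across the outer folds."""
        out: dict[str, dict[str, dict[str, float]]] = {}
        for block in ("flapping", "jumping", "macro"):
            out[block] = {}
            for metric in METRIC_NAMES:
                vals = [getattr(getattr(f.report, block), metric) for f in self.folds]
                out[block][metric] = {
                    "mean": float(np.mean(vals)),
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                }
        return out


def _label_bits(labels: Sequence, index: int) -> np.ndarray:
    rows = []
    for lv in labels:
        if isinstance(lv, LabelVector):
            rows.append(lv.as_tuple()[index])
        else:
            rows.append(int(np.asarray(lv)[index]))
    return np.array(rows, dtype=int)


def confusion(predictions: Sequence, truths: Sequence, label: str) -> ConfusionCounts:
    """Confusion counts for one label bit over aligned prediction/truth
    lists (items may be :class:`LabelVector` or length-2 arrays)."""
    if len(predictions) != len(truths):
        raise ValidationError(
            f"got {len(predictions)} predictions for {len(truths)} truths"
        )
    if label not in LABEL_NAMES:
        raise ValidationError(f"unknown label {label!r}")
    idx = LABEL_NAMES.index(label)
    pred = _label_bits(predictions, idx)
    true = _label_bits(truths, idx)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
    )


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("%s is 0/0; reporting 0", what)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricBlock:
    """The five evaluation metrics from confusion counts.

    accuracy = (TP+TN)/(P+N); recall = TP/(TP+FN);
    specificity = TN/(TN+FP); precision = TP/(TP+FP);
    F1 = 2TP/(2TP+FP+FN). A 0/0 denominator yields 0 with a warning.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics over zero windows")
    return MetricBlock(
        accuracy=(c.tp + c.tn) / c.total,
        recall=_ratio(c.tp, c.tp + c.fn, "recall"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        precision=_ratio(c.tp, c.tp + c.fp, "precision"),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
    )


def macro_average(flapping: MetricBlock, jumping: MetricBlock) -> MetricBlock:
    """Unweighted mean of the two per-label blocks."""
    return MetricBlock(**{
        m: (getattr(flapping, m) + getattr(jumping, m)) / 2.0
        for m in METRIC_NAMES
    })


def round3(value: float) -> float:
    """Round to 3 decimals for reporting, resolving exact half-ties
    downward (the convention under which the published macro table's tie
    cases reproduce from its printed per-label values)."""
    d = Decimal(f"{value:.10f}").quantize(Decimal("0.001"), rounding=ROUND_HALF_DOWN)
    return float(d)


def printed(block: MetricBlock) -> dict[str, float]:
    """The block as it would appear in a results table (3 decimals)."""
    return {m: round3(v) for m, v in block.as_dict().items()}


def report_from_predictions(predictions: Sequence, truths: Sequence) -> MetricsReport:
    blocks = {
        name: metrics(confusion(predictions, truths, name)) for name in LABEL_NAMES
    }
    return MetricsReport(
        flapping=blocks["flapping"],
        jumping=blocks["jumping"],
        macro=macro_average(blocks["flapping"], blocks["jumping"]),
    )


def _powerset_classes(windows: Sequence[Window]) -> np.ndarray:
    return np.array([w.label.powerset_class for w in windows])


def stratified_group_kfold(
    windows: Sequence[Window],
    k: int = 3,
    mode: str = "subject_wise",
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Outer-loop folds as (train_indices, test_indices) pairs.

    ``subject_wise`` keeps every subject's windows within one fold while
    balancing the label-powerset strata across folds; ``random`` ignores
    subjects and stratifies windows directly (the optimistic comparison
    mode). Deterministic given the seed.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    y = _powerset_classes(windows)
    if mode == "subject_wise":
        groups = np.array([w.subject_id for w in windows])
        if len(set(groups)) < k:
            raise ValidationError(
                f"subject-wise {k}-fold split needs >= {k} subjects, "
                f"got {len(set(groups))}"
            )
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [
            (train, test) for train, test in splitter.split(np.zeros(len(y)), y, groups)
        ]
        for train, test in folds:  # hard leakage guard
            overlap = set(groups[train]) & set(groups[test])
            assert not overlap, f"subject leakage across folds: {sorted(overlap)}"
        return folds
    if mode == "random":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(train, test) for train, test in splitter.split(np.zeros(len(y)), y)]
    raise ValidationError(f"unknown split mode {mode!r}")


def _inner_split(
    windows: Sequence[Window], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified validation split (~1/3) for the tuner.

    Grouped by subject when enough subjects are available for at least
    two per side; otherwise a plain stratified split over windows.
    """
    subjects = {w.subject_id for w in windows}
    if len(subjects) >= 4:
        folds = stratified_group_kfold(windows, k=3, mode="subject_wise", seed=seed)
        return folds[0]
    y = _powerset_classes(windows)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= 3:
        folds = stratified_group_kfold(windows, k=3, mode="random", seed=seed)
        return folds[0]
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(windows))
    n_val = max(1, len(windows) // 3)
    return idx[n_val:], idx[:n_val]


def _score(net: LSTMNetwork, X: np.ndarray, Y: np.ndarray) -> float:
    preds = net.predict(X)
    report = report_from_predictions(preds, Y)
    return report.macro.f1


def tune(
    windows: Sequence[Window],
    space: SearchSpace,
    budget: int,
    seed: int,
    base_config: NetworkConfig,
) -> tuple[HyperparameterSet, list[dict]]:
    """Budgeted successive halving over the discrete search space.

    ``budget`` configurations are sampled uniformly (without replacement
    when the space allows); each trains for a small epoch allowance on an
    inner train/validation split and is scored by validation macro F1.
    The top third survives with a tripled allowance until one remains or
    the allowance reaches the base config's epochs. Ties keep the
    earlier-sampled configuration. Returns the winner and the full
    evaluation log.
    """
    if not windows:
        raise ValidationError("cannot tune on empty training data")
    if budget < 1:
        raise ValidationError("budget must admit at least one configuration")
    rng = np.random.default_rng(seed)
    grid = space.all_configurations()
    if budget >= len(grid):
        candidates = list(grid)
    else:
        idx = rng.choice(len(grid), size=budget, replace=False)
        candidates = [grid[i] for i in sorted(idx)]

    train_idx, val_idx = _inner_split(windows, seed)
    inner_train = [windows[i] for i in train_idx]
    inner_val = [windows[i] for i in val_idx]
    Xtr, Ytr, _ = windows_to_arrays(inner_train)
    Xva, Yva, _ = windows_to_arrays(inner_val)

    epoch_cap = max(1, base_config.epochs)
    epochs = max(1, epoch_cap // 9)
    log_rows: list[dict] = []
    ranked = list(enumerate(candidates))  # (sample order, hp)
    from dataclasses import replace as _replace
    while True:
        scored = []
        for order, hp in ranked:
            cfg = _replace(hp.apply(base_config), epochs=epochs, seed=seed)
            net, _ = train(Xtr, Ytr, cfg)
            s = _score(net, Xva, Yva)
            scored.append((s, -order, order, hp))
            log_rows.append({"hp": hp, "epochs": epochs, "score": s, "order": order})
        scored.sort(reverse=True)  # best score first; ties -> earlier order
        if len(scored) == 1 or epochs >= epoch_cap:
            break
        keep = max(1, math.ceil(len(scored) / 3))
        ranked = [(order, hp) for _, _, order, hp in scored[:keep]]
        epochs = min(epoch_cap, epochs * 3)
    best = scored[0][3]
    return best, log_rows


def mean_hyperparameters(bests: Sequence[HyperparameterSet]) -> HyperparameterSet:
    """Deployment rule: average the per-fold winners.

    Integer fields round half-to-even to the nearest integer; the dropout
    rate is the mean rounded to 3 decimals.
    """
    if not bests:
        raise ValidationError("need at least one fold's best hyperparameters")
    n = len(bests)
    return HyperparameterSet(
        units_layer_1=round(sum(b.units_layer_1 for b in bests) / n),
        units_layer_2=round(sum(b.units_layer_2 for b in bests) / n),
        units_layer_3=round(sum(b.units_layer_3 for b in bests) / n),
        dropout_rate=round(sum(b.dropout_rate for b in bests) / n, 3),
        batch_size=round(sum(b.batch_size for b in bests) / n),
    )


def nested_cv(
    windows: Sequence[Window],
    k: int = 3,
    mode: str = "subject_wise",
    seed: int = 0,
    base_config: NetworkConfig | None = None,
    space: SearchSpace | None = None,
    budget: int = 4,
) -> CVResult:
    """Nested cross-validation: tune inside each outer-training set, then
    retrain the fold winner on that whole set and score it on the outer
    test set."""
    if base_config is None:
        from .model import desk_config
        base_config = desk_config(seed=seed)
    if space is None:
        space = desk_space()
    folds = stratified_group_kfold(windows, k=k, mode=mode, seed=seed)
    results: list[FoldResult] = []
    for f, (train_idx, test_idx) in enumerate(folds):
        fold_seed = (seed * 1009 + f) % (2 ** 31)
        outer_train = [windows[i] for i in train_idx]
        outer_test = [windows[i] for i in test_idx]
        best, _ = tune(outer_train, space, budget, fold_seed, base_config)
        from dataclasses import replace as _replace
        cfg = _replace(best.apply(base_config), seed=fold_seed)
        Xtr, Ytr, _ = windows_to_arrays(outer_train)
        Xte, Yte, _ = windows_to_arrays(outer_test)
        net, _ = train(Xtr, Ytr, cfg)
        preds = net.predict(Xte)
        report = report_from_predictions(preds, Yte)
        results.append(FoldResult(
            fold=f,
            best=best,
            report=report,
            train_subjects=sorted({w.subject_id for w in outer_train}),
            test_subjects=sorted({w.subject_id for w in outer_test}),
        ))
        log.info(
            "fold %d: best=%s macro_accuracy=%.3f macro_f1=%.3f",
            f, best, report.macro.accuracy, report.macro.f1,
        )
    return CVResult(mode=mode, folds=results)


def train_deployment(
    windows: Sequence[Window],
    hp: HyperparameterSet,
    base_config: NetworkConfig,
    seed: int = 0,
) -> tuple[LSTMNetwork, MetricsReport]:
    """Train the final model on all windows with the averaged
    hyperparameters; returns it with metrics on the (held-in) data."""
    if not windows:
        raise ValidationError("cannot train a deployment model on no windows")
    from dataclasses import replace as _replace
    cfg = _replace(hp.apply(base_config), seed=seed)
    X, Y, _ = windows_to_arrays(windows)
    net, _ = train(X, Y, cfg)
    report = report_from_predictions(net.predict(X), Y)
    return net, report
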