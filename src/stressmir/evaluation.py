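"""Performance evaluation: metric suite, class balancing and cross-validation.

The metric suite follows the convention of balanced binary sequence
classification: sensitivity Sen = TP/(TP+FN), specificity Spe = TN/(TN+FP),
accuracy as the balanced mean Acc = (Sen+Spe)/2, precision Pre = TP/(TP+FP)
and F-score = 2TP/(2TP+FP+FN), all reported as percentages, plus the area
under the ROC curve (trapezoid) and under the precision-recall curve
(step-wise interpolation).  Cross-validation offers stratified k-fold (the
positive and negative sets are partitioned separately, then unioned per
fold) and leave-one-out.  Threshold metrics are averaged over folds, while
auROC/auPRC are computed on the pooled held-out scores — pooling keeps the
curves well-defined for leave-one-out and stabilizes small folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .classifier import SVMConfig, decision_values, predict, train
from .errors import DataError, ValidationError
from .pseknc import FeatureMatrix


@dataclass
class MetricsBundle:
    """Confusion counts, the seven derived metrics and both curves.

    Threshold metrics are percentages in [0, 100]; a metric whose
    denominator is zero is NaN.  ``roc_points`` / ``pr_points`` are
    (x, y) coordinate arrays; they are empty when only counts are known.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sen: float
    spe: float
    acc: float
    pre: float
    f_score: float
    auroc: float = float("nan")
    auprc: float = float("nan")
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    pr_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "MetricsBundle":
        sen = _rate(tp, tp + fn)
        spe = _rate(tn, tn + fp)
        return cls(
            tp=tp,
            tn=tn,
            fp=fp,
            fn=fn,
            sen=sen,
            spe=spe,
            acc=(sen + spe) / 2.0,
            pre=_rate(tp, tp + fp),
            f_score=_rate(2 * tp, 2 * tp + fp + fn),
        )

    def rounded(self) -> dict[str, float]:
        """Two-decimal (round-half-even) report values; raw floats retained."""
        return {
            name: round(getattr(self, name), 2)
            for name in ("sen", "spe", "acc", "pre", "f_score", "auroc", "auprc")
        }

    def to_row(self) -> dict:
        row: dict = {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}
        row.update(
            {
                "Sen": self.sen,
                "Spe": self.spe,
                "Acc": self.acc,
                "Pre": self.pre,
                "F-score": self.f_score,
                "auROC": self.auroc,
                "auPRC": self.auprc,
            }
        )
        return row


def _rate(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def balanced_accuracy(sen: float, spe: float) -> float:
    """Acc = (Sen + Spe) / 2, on whatever scale its inputs use."""
    return (sen + spe) / 2.0


def f_score_from_rates(pre: float, sen: float) -> float:
    """Harmonic mean of precision and sensitivity (equals 2TP/(2TP+FP+FN))."""
    return 2.0 * pre * sen / (pre + sen)


def threshold_metrics(labels, scores, threshold: float = 0.5) -> MetricsBundle:
    """Confusion counts and the five threshold metrics only (no curves).

    Defined even for single-class truth (NaN where a denominator is zero).
    """
    y = _as01(labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValidationError(f"{len(y)} labels vs {len(s)} scores")
    pred = (s >= threshold).astype(int)
    return MetricsBundle.from_counts(
        tp=int(np.sum((y == 1) & (pred == 1))),
        tn=int(np.sum((y == 0) & (pred == 0))),
        fp=int(np.sum((y == 0) & (pred == 1))),
        fn=int(np.sum((y == 1) & (pred == 0))),
    )


def compute_metrics(
    labels, scores, threshold: float = 0.5
) -> MetricsBundle:
    """Full metric bundle from truth labels and positive-class scores.

    ``labels`` may be 1/0 integers or 'positive'/'negative' strings.  The
    ROC curve sweeps the unique score thresholds (trapezoid area); the PR
    curve uses step-wise interpolation for its area.  Curve metrics require
    both classes in the truth; threshold metrics are returned regardless,
    NaN where a denominator vanishes.
    """
    y = _as01(labels)
    s = np.asarray(scores, dtype=float)
    bundle = threshold_metrics(y, s, threshold)
    if len(np.unique(y)) < 2:
        raise DataError(
            "ROC/PR curves need at least one positive and one negative example"
        )
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    bundle.auroc = 100.0 * auc(fpr, tpr)
    bundle.auprc = 100.0 * average_precision_score(y, s)
    bundle.roc_points = np.column_stack([fpr, tpr])
    bundle.pr_points = np.column_stack([recall, precision])
    return bundle


def _as01(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return arr.astype(int)
    return np.array([1 if lab == "positive" else 0 for lab in arr])


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def balance_dataset(matrix: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Undersample the majority class to match the minority, seeded.

    All minority rows are kept; majority rows are drawn uniformly without
    replacement.  Row order of the original matrix is preserved.  An
    already-balanced matrix is returned unchanged.
    """
    y = matrix.y()
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("balancing requires both classes present")
    if n_pos == n_neg:
        return matrix
    minority = 1 if n_pos < n_neg else 0
    maj_idx = np.flatnonzero(y != minority)
    keep_maj = np.random.default_rng(seed).choice(
        maj_idx, size=min(n_pos, n_neg), replace=False
    )
    keep = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
    return matrix.subset_rows(keep)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Outcome of one cross-validation run.

    ``fold_metrics`` holds one bundle per fold for k-fold (empty for
    leave-one-out, whose metrics only exist pooled); ``aggregate`` averages
    the threshold metrics over folds and computes auROC/auPRC on the pooled
    held-out scores.  ``fold_assignment`` maps row id -> fold index and
    ``pooled_scores`` maps row id -> held-out positive-class score.
    """

    scheme: str
    aggregate: MetricsBundle
    fold_metrics: list[MetricsBundle]
    fold_assignment: dict[str, int]
    pooled_scores: dict[str, float]
    seed: int | None = None


def _fit_scores(
    train_matrix: FeatureMatrix,
    test_matrix: FeatureMatrix,
    config: SVMConfig,
    probability: bool,
) -> np.ndarray:
    model = train(train_matrix, config)
    if probability:
        return predict(model, test_matrix)["probability_positive"].to_numpy()
    return decision_values(model, test_matrix)


def kfold_cv(
    matrix: FeatureMatrix,
    k: int = 5,
    model_config: SVMConfig | None = None,
    seed: int = 0,
    probability: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation.

    Each class is shuffled (seeded) and split into k near-equal subsets;
    fold i unites subset i of each class, is held out once, and the model
    trains on the rest.  With ``probability=False`` raw decision values are
    pooled instead of Platt probabilities (faster; identical ranking, so
    identical auROC/auPRC) and the hard-call threshold becomes 0.
    """
    if model_config is None:
        model_config = SVMConfig()
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    y = matrix.y()
    if np.bincount(y, minlength=2).min() < k:
        raise DataError(f"each class needs >= {k} examples for {k}-fold CV")
    threshold = 0.5 if probability else 0.0
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment: dict[str, int] = {}
    fold_metrics: list[MetricsBundle] = []
    pooled = np.empty(len(y))
    for fold, (tr, te) in enumerate(splitter.split(matrix.X, y)):
        scores = _fit_scores(
            matrix.subset_rows(tr),
            matrix.subset_rows(te),
            replace_seed(model_config, model_config.seed, probability),
            probability,
        )
        pooled[te] = scores
        for i in te:
            fold_assignment[matrix.ids[i]] = fold
        if len(np.unique(y[te])) == 2:
            fold_metrics.append(compute_metrics(y[te], scores, threshold))
        else:  # degenerate single-class fold: threshold metrics only
            fold_metrics.append(threshold_metrics(y[te], scores, threshold))
    aggregate = _aggregate(y, pooled, fold_metrics, threshold)
    return CVResult(
        scheme="fivefold" if k == 5 else f"{k}fold",
        aggregate=aggregate,
        fold_metrics=fold_metrics,
        fold_assignment=fold_assignment,
        pooled_scores=dict(zip(matrix.ids, pooled)),
        seed=seed,
    )


def replace_seed(config: SVMConfig, seed: int, probability: bool) -> SVMConfig:
    return SVMConfig(C=config.C, gamma=config.gamma, probability=probability, seed=seed)


def _aggregate(
    y: np.ndarray,
    pooled: np.ndarray,
    fold_metrics: list[MetricsBundle],
    threshold: float,
) -> MetricsBundle:
    bundle = compute_metrics(y, pooled, threshold)
    if fold_metrics:
        # threshold metrics: mean over folds; counts stay the pooled totals
        for name in ("sen", "spe", "pre", "f_score"):
            setattr(bundle, name, float(np.nanmean([getattr(m, name) for m in fold_metrics])))
        bundle.acc = balanced_accuracy(bundle.sen, bundle.spe)
    return bundle


def loocv(
    matrix: FeatureMatrix,
    model_config: SVMConfig | None = None,
    probability: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation: deterministic, no fold seed.

    Metrics are computed once on the n pooled held-out predictions.
    """
    if model_config is None:
        model_config = SVMConfig()
    y = matrix.y()
    if len(y) < 3:
        raise DataError(f"leave-one-out needs n >= 3, got {len(y)}")
    threshold = 0.5 if probability else 0.0
    pooled = np.empty(len(y))
    all_idx = np.arange(len(y))
    for i in all_idx:
        tr = np.delete(all_idx, i)
        pooled[i] = _fit_scores(
            matrix.subset_rows(tr),
            matrix.subset_rows([i]),
            replace_seed(model_config, model_config.seed, probability),
            probability,
        )[0]
    return CVResult(
        scheme="loocv",
        aggregate=compute_metrics(y, pooled, threshold),
        fold_metrics=[],
        fold_assignment={rid: i for i, rid in enumerate(matrix.ids)},
        pooled_scores=dict(zip(matrix.ids, pooled)),
        seed=None,
    )
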