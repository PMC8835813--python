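"""SVM-RFE feature ranking and incremental subset selection.

Recursive feature elimination fits a linear-kernel SVM on the surviving
features, scores each feature by the squared component of the weight vector
w = sum_i alpha_i y_i x_i, removes the lowest-scoring features, and repeats
until none remain; the final ranking is the reverse removal order (the last
features standing are the most informative).  The weight vector is only
defined for the linear kernel, so elimination always uses it even though
final classification uses the RBF kernel.

The subset size is then chosen by sweeping the ranking in increments
(default 10 features at a time), scoring each prefix by cross-validated
auROC/auPRC with an RBF SVM at default parameters, and keeping the size
with the best auROC (ties: higher auPRC, then smaller size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classifier import SVMConfig
from .errors import DataError, ValidationError
from .pseknc import FeatureMatrix


@dataclass
class RFERanking:
    """Total order over feature names, best first, plus the elimination log.

    ``elimination_log[i]`` lists the features removed at iteration i (worst
    first within the iteration); ``weights_last_iteration`` maps each
    feature to its squared weight at the moment it was removed.
    """

    ranked_features: list[str]
    elimination_log: list[list[str]]
    weights_last_iteration: dict[str, float]

    def top(self, m: int) -> list[str]:
        return self.ranked_features[:m]


@dataclass
class SelectionCurve:
    """auROC/auPRC as a function of ranked-prefix size, and the chosen size."""

    subset_sizes: list[int]
    auroc: list[float]
    auprc: list[float]
    chosen_size: int
    chosen_features: list[str]


def rfe_rank(matrix: FeatureMatrix, step: int = 1, C: float = 1.0) -> RFERanking:
    """Rank features by recursive elimination with a linear SVM.

    ``step`` features are removed per iteration (the remainder all at once
    when fewer survive).  w^2 ties break by original column order (stable
    sort), making the ranking deterministic.
    """
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    if step >= matrix.p:
        raise DataError(
            f"step {step} would eliminate all {matrix.p} features in one "
            "iteration, leaving no ranking"
        )
    y = matrix.y()
    if len(np.unique(y)) < 2:
        raise DataError("ranking requires both classes present")
    # standardized features: w^2 compares columns on a common scale
    X = StandardScaler().fit_transform(matrix.X)
    surviving = list(range(matrix.p))
    removal_order: list[int] = []  # worst first
    elimination_log: list[list[str]] = []
    removal_weight: dict[str, float] = {}
    while surviving:
        est = SVC(kernel="linear", C=C)
        est.fit(X[:, surviving], y)
        w2 = np.asarray(est.coef_).ravel() ** 2
        order = np.argsort(w2, kind="stable")  # ascending, ties by column order
        n_drop = min(step, len(surviving)) if len(surviving) > step else len(surviving)
        dropped_local = order[:n_drop]
        dropped = [surviving[i] for i in dropped_local]
        elimination_log.append([matrix.feature_names[i] for i in dropped])
        for loc, col in zip(dropped_local, dropped):
            removal_weight[matrix.feature_names[col]] = float(w2[loc])
        removal_order.extend(dropped)
        surviving = [c for c in surviving if c not in set(dropped)]
    ranked = [matrix.feature_names[c] for c in reversed(removal_order)]
    return RFERanking(
        ranked_features=ranked,
        elimination_log=elimination_log,
        weights_last_iteration=removal_weight,
    )


def selection_curve(
    matrix: FeatureMatrix,
    ranking: RFERanking,
    grid_step: int = 10,
    folds: int = 5,
    seed: int = 0,
    model_config: SVMConfig | None = None,
) -> SelectionCurve:
    """Score ranked-prefix subsets by k-fold CV and pick the best size.

    Sizes are grid_step, 2*grid_step, ... up to the full feature count
    (included even when it is not a multiple of grid_step).
    """
    from .evaluation import kfold_cv  # local import to avoid a cycle

    if grid_step < 1:
        raise ValidationError(f"grid_step must be >= 1, got {grid_step}")
    p = len(ranking.ranked_features)
    sizes = list(range(grid_step, p + 1, grid_step))
    if not sizes or sizes[-1] != p:
        sizes.append(p)
    aurocs: list[float] = []
    auprcs: list[float] = []
    for size in sizes:
        sub = matrix.select(ranking.top(size))
        result = kfold_cv(sub, k=folds, model_config=model_config, seed=seed, probability=False)
        aurocs.append(result.aggregate.auroc)
        auprcs.append(result.aggregate.auprc)
    # max auROC; ties -> higher auPRC, then smaller size (scan order settles it)
    best = 0
    for i in range(1, len(sizes)):
        if aurocs[i] > aurocs[best] or (
            aurocs[i] == aurocs[best] and auprcs[i] > auprcs[best]
        ):
            best = i
    return SelectionCurve(
        subset_sizes=sizes,
        auroc=aurocs,
        auprc=auprcs,
        chosen_size=sizes[best],
        chosen_features=ranking.top(sizes[best]),
    )


def subsample_for_selection(
    matrix: FeatureMatrix, fraction: float = 0.5, seed: int = 0
) -> FeatureMatrix:
    """Stratified random row subset used for the selection stage.

    Running elimination on a held-aside fraction (default half) of the
    training data keeps the subsequent cross-validated subset scoring from
    overfitting the selection to the full training set.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return matrix
    y = matrix.y()
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_keep = max(1, int(round(fraction * len(idx))))
        keep.extend(rng.choice(idx, size=n_keep, replace=False))
    return matrix.subset_rows(np.sort(keep))
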