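"""Rank features by SVM recursive feature elimination and pick a subset size.

A planted-signal dataset (10 informative + 90 noise features) shows the two
stages: RFE orders features by their squared linear-SVM weight across
elimination rounds, then cross-validated auROC over growing ranked prefixes
selects how many features to keep.
"""

import numpy as np

import stressmir as sm

rng = np.random.default_rng(7)
n, informative, noise = 120, 10, 90
y = np.repeat([1, 0], n // 2)
X = rng.normal(size=(n, informative + noise))
X[:, :informative] += np.outer(y, np.full(informative, 1.2))

matrix = sm.FeatureMatrix(
    X,
    [f"signal{j}" if j < informative else f"noise{j}" for j in range(X.shape[1])],
    [f"seq{i}" for i in range(n)],
    ["positive" if t else "negative" for t in y],
)

ranking = sm.rfe_rank(matrix, step=5)
print("top 10 ranked features:", ranking.ranked_features[:10])

curve = sm.selection_curve(matrix, ranking, grid_step=20, folds=5, seed=7)
for size, auroc, auprc in zip(curve.subset_sizes, curve.auroc, curve.auprc):
    marker = "  <- chosen" if size == curve.chosen_size else ""
    print(f"  {size:3d} features: auROC={auroc:6.2f}  auPRC={auprc:6.2f}{marker}")

# Most planted `signal*` features surface at the top of the ranking, and the
# curve typically peaks at a compact prefix rather than the full feature set —
# noise features dilute the kernel.
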