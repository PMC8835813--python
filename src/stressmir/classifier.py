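"""RBF-kernel support vector classification over PseKNC feature matrices.

A standard max-margin SVM solver (scikit-learn's libsvm binding) stands
behind this module's contract: training solves the soft-margin dual with
kernel K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2) under the constraints
sum_i alpha_i y_i = 0 and 0 <= alpha_i <= C, and probabilities come from a
Platt-style monotone sigmoid over the decision values, fitted on training
folds.  The defaults mirror common practice for this kind of sequence
classifier: C = 1 and gamma = 1 / n_features, with an optional log-grid
search over powers of two for both.

Any learner exposing ``fit(X, y)`` and ``predict_proba`` can be plugged
into the same pipeline via :func:`train`'s ``learner_factory`` argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError, ValidationError
from .pseknc import FeatureMatrix

MODEL_FORMAT_VERSION = "stressmir-model-1"


@dataclass(frozen=True)
class SVMConfig:
    """Kernel and solver settings.

    ``gamma=None`` means the conventional default 1/#features, resolved at
    fit time against the training matrix.
    """

    C: float = 1.0
    gamma: float | None = None
    probability: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError(f"C must be > 0, got {self.C}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


@dataclass
class ModelArtifact:
    """A trained classifier plus everything needed to apply it faithfully.

    ``estimator`` is the fitted solver object; for the SVM the dual
    coefficients alpha_i*y_i and bias live inside it and are exposed through
    :attr:`dual_coef` and :attr:`intercept`.  ``platt`` holds the (A, B) of
    the probability sigmoid p = 1/(1 + exp(A*f + B)) fitted on held-out
    decision values of the training set (A < 0, so probability is strictly
    increasing in the margin f).  Prediction requires exactly
    ``feature_names`` in order, and refuses matrices encoded under a
    different encoder fingerprint.
    """

    estimator: object
    config: SVMConfig
    feature_names: list[str]
    n_pos: int
    n_neg: int
    scaler: StandardScaler | None = None
    platt: tuple[float, float] | None = None
    encoder_fingerprint: dict | None = None
    format_version: str = MODEL_FORMAT_VERSION
    extra: dict = field(default_factory=dict)

    @property
    def dual_coef(self) -> np.ndarray:
        """alpha_i * y_i for the support vectors (SVM only)."""
        return self.estimator.dual_coef_[0]

    @property
    def intercept(self) -> float:
        return float(self.estimator.intercept_[0])

    @property
    def platt_params(self) -> tuple[float, float]:
        """(A, B) of the sigmoid p = 1/(1+exp(A*f + B)) on decision values."""
        if self.platt is None:
            raise ValidationError("model was trained without probability calibration")
        return self.platt

    def save(self, path) -> None:
        joblib.dump({"format_version": self.format_version, "artifact": self}, path)

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        payload = joblib.load(path)
        version = payload.get("format_version") if isinstance(payload, dict) else None
        if version != MODEL_FORMAT_VERSION:
            raise ValidationError(
                f"model file {path} has format {version!r}; "
                f"this build reads {MODEL_FORMAT_VERSION!r}"
            )
        return payload["artifact"]


def _check_trainable(matrix: FeatureMatrix) -> np.ndarray:
    y = matrix.y()
    if len(np.unique(y)) < 2:
        raise DataError("training requires both classes present")
    if np.bincount(y, minlength=2).min() < 2:
        raise DataError("training requires at least 2 examples per class")
    if not np.all(np.isfinite(matrix.X)):
        raise DataError("training matrix contains non-finite values")
    return y


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit p = 1/(1+exp(A*f+B)) by maximum likelihood (Platt scaling).

    Platt's smoothed targets guard against overconfidence on separable data,
    and A is constrained non-positive so the fitted probability is a
    monotone non-decreasing function of the decision value (strictly
    increasing whenever the decision values carry any signal).
    """
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_and_grad(params: np.ndarray):
        z = params[0] * decision + params[1]
        # -sum[t*log(p) + (1-t)*log(1-p)] with p = 1/(1+exp(z))
        nll = float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))
        gz = expit(z) - (1.0 - t)
        return nll, np.array([np.dot(gz, decision), gz.sum()])

    result = minimize(
        nll_and_grad,
        x0=np.array([-1.0, 0.0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, 0.0), (None, None)],
    )
    return float(result.x[0]), float(result.x[1])


def _platt_probability(decision: np.ndarray, platt: tuple[float, float]) -> np.ndarray:
    a, b = platt
    z = a * np.asarray(decision, dtype=float) + b
    return expit(-z)


def _make_svc(config: SVMConfig, n_features: int) -> SVC:
    return SVC(C=config.C, kernel="rbf", gamma=config.resolve_gamma(n_features))


def _cv_decision_values(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> np.ndarray:
    """Held-out decision values for Platt fitting (stratified internal CV).

    Standardization is refit inside each fold so the held-out values mimic
    genuine prediction.
    """
    k = min(5, int(np.bincount(y, minlength=2).min()))
    if k < 2:
        raise DataError("probability calibration needs >= 2 examples per class")
    out = np.empty(len(y))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    for tr, te in splitter.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        est = _make_svc(config, X.shape[1])
        est.fit(scaler.transform(X[tr]), y[tr])
        out[te] = est.decision_function(scaler.transform(X[te]))
    return out


def train(
    matrix: FeatureMatrix,
    config: SVMConfig | None = None,
    encoder_fingerprint: dict | None = None,
    learner_factory=None,
) -> ModelArtifact:
    """Fit the classifier on a labeled feature matrix.

    Deterministic given ``config.seed`` and row order.  ``learner_factory``
    (config -> unfitted estimator with fit/predict_proba) swaps in an
    alternative learner behind the same artifact contract.
    """
    if config is None:
        config = SVMConfig()
    y = _check_trainable(matrix)
    # features are standardized before fitting (zero mean, unit variance per
    # column, learned from the training set) so the default gamma = 1/p puts
    # the RBF kernel in a responsive range regardless of raw feature scale
    scaler = StandardScaler().fit(matrix.X)
    Xs = scaler.transform(matrix.X)
    platt = None
    if learner_factory is not None:
        est = learner_factory(config)
    else:
        est = _make_svc(config, matrix.p)
        if config.probability:
            platt = _fit_platt(_cv_decision_values(matrix.X, y, config), y)
    est.fit(Xs, y)
    return ModelArtifact(
        estimator=est,
        config=config,
        feature_names=list(matrix.feature_names),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        scaler=scaler,
        platt=platt,
        encoder_fingerprint=encoder_fingerprint,
    )


def _aligned_X(model: ModelArtifact, matrix: FeatureMatrix) -> np.ndarray:
    index = {f: i for i, f in enumerate(matrix.feature_names)}
    missing = [f for f in model.feature_names if f not in index]
    if missing:
        raise ValidationError(
            f"matrix lacks {len(missing)} feature(s) the model needs "
            f"(first: {missing[:5]})"
        )
    X = matrix.X[:, [index[f] for f in model.feature_names]]
    return model.scaler.transform(X) if model.scaler is not None else X


def predict(
    model: ModelArtifact,
    matrix: FeatureMatrix,
    encoder_fingerprint: dict | None = None,
) -> pd.DataFrame:
    """Per-row positive-class probability and hard call at threshold 0.5.

    Probabilities are monotone in the decision value, so ranking rows by
    probability and by margin agree.
    """
    if (
        encoder_fingerprint is not None
        and model.encoder_fingerprint is not None
        and encoder_fingerprint != model.encoder_fingerprint
    ):
        raise ValidationError(
            "encoder configuration differs from the one the model was trained "
            f"with: {encoder_fingerprint} != {model.encoder_fingerprint}"
        )
    X = _aligned_X(model, matrix)
    if model.platt is not None:
        proba = _platt_probability(model.estimator.decision_function(X), model.platt)
    else:  # plug-in learner with native probabilities
        proba = model.estimator.predict_proba(X)[:, 1]
    return pd.DataFrame(
        {
            "id": matrix.ids,
            "predicted_class": np.where(proba >= 0.5, "positive", "negative"),
            "probability_positive": proba,
        }
    )


def decision_values(model: ModelArtifact, matrix: FeatureMatrix) -> np.ndarray:
    """Raw signed margins f(x); positive means the positive class."""
    return model.estimator.decision_function(_aligned_X(model, matrix))


def grid_search(
    matrix: FeatureMatrix,
    exponent_range: tuple[int, int] = (-5, 5),
    step: int = 2,
    folds: int = 5,
    seed: int = 0,
    include_default: bool = False,
) -> SVMConfig:
    """Pick (gamma, C) = (2^a, 2^b) maximizing cross-validated auROC.

    The default exponents -5..5 with step 2 give 6 values per axis, 36
    candidate pairs.  Ties break toward smaller C, then smaller gamma.
    ``include_default`` adds (1/#features, 1) as an extra candidate.
    """
    lo, hi = exponent_range
    exponents = list(range(lo, hi + 1, step))
    if not exponents:
        raise ValidationError(f"empty grid: exponent range {exponent_range} step {step}")
    y = _check_trainable(matrix)
    candidates = sorted(
        {(2.0**b, 2.0**a) for a, b in itertools.product(exponents, repeat=2)}
    )
    if include_default:
        candidates.append((1.0, 1.0 / matrix.p))
        candidates.sort()
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(splitter.split(matrix.X, y))
    best: tuple[float, float] | None = None
    best_score = -np.inf
    scaled = [
        (StandardScaler().fit(matrix.X[tr]), tr, te) for tr, te in split
    ]
    for C, gamma in candidates:  # (C, gamma) ascending: first strict max wins ties
        scores = np.empty(len(y))
        for scaler, tr, te in scaled:
            est = SVC(C=C, kernel="rbf", gamma=gamma)
            est.fit(scaler.transform(matrix.X[tr]), y[tr])
            scores[te] = est.decision_function(scaler.transform(matrix.X[te]))
        score = roc_auc_score(y, scores)
        if score > best_score:
            best_score = score
            best = (C, gamma)
    return SVMConfig(C=best[0], gamma=best[1], probability=True, seed=seed)
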