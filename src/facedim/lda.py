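"""Two-class linear discriminant with a continuous gender score.

The classifier is solved from first principles: the weight vector is the
pooled within-class covariance inverse applied to the class-mean
difference, w = Σ_p⁻¹(μ₊ − μ₋), and the threshold is the midpoint of the
projected class means shifted by the log prior ratio. The *gender score*
of a face is its signed distance term wᵀx − threshold: positive means the
face falls on the positive-class (male) side of the discriminant
hyperplane, and its magnitude measures how far.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

#: Default shuffle seed for stratified cross-validation folds.
DEFAULT_CV_SEED = 20150415


class GenderLDA(BaseEstimator, ClassifierMixin):
    """Two-class LDA with pooled covariance, equal priors by default.

    Parameters
    ----------
    priors : "equal" or "proportional"
        Class priors entering the threshold's log prior-ratio shift.
        Equal priors match per-class accuracy reporting on near-balanced
        cohorts; proportional uses training class frequencies.
    positive_class : optional label
        The class scored positive (``classes_[-1]``, i.e. lexicographically
        last, when None — which makes "male" positive against "female").
    ridge : float
        Relative ridge λ·trace(Σ)/p added when the pooled covariance is
        singular or ill-conditioned.

    Attributes
    ----------
    classes_ : (2,) array of labels, negative class first.
    means_ : (2, p) per-class feature means.
    covariance_ : (p, p) pooled within-class covariance.
    coef_ : (p,) weight vector Σ⁻¹(μ₊ − μ₋).
    threshold_ : scalar decision point in score space.
    """

    def __init__(self, priors: str = "equal", positive_class=None, ridge: float = 1e-6):
        self.priors = priors
        self.positive_class = positive_class
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"GenderLDA needs exactly 2 classes, got {len(classes)}")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.positive_class is not None:
            if self.positive_class not in classes:
                raise ValueError(f"positive_class {self.positive_class!r} not in labels")
            neg = classes[classes != self.positive_class][0]
            classes = np.array([neg, self.positive_class])
        self.classes_ = classes
        n, p = X.shape

        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        pooled = np.zeros((p, p))
        for c in classes:
            xc = X[y == c] - X[y == c].mean(axis=0)
            pooled += xc.T @ xc
        pooled /= n - 2

        # regularise if singular / ill-conditioned (or if n <= p)
        cond = np.linalg.cond(pooled)
        if not np.isfinite(cond) or cond > 1e12 or n <= p + 2:
            lam = self.ridge * np.trace(pooled) / p
            pooled = pooled + lam * np.eye(p)
            warnings.warn(
                f"ill-conditioned pooled covariance; ridge {lam:.3g} applied",
                stacklevel=2,
            )

        if self.priors == "equal":
            priors = np.array([0.5, 0.5])
        elif self.priors == "proportional":
            order = [int(np.flatnonzero(np.unique(y) == c)[0]) for c in classes]
            priors = counts[order] / n
        else:
            raise ValueError("priors must be 'equal' or 'proportional'")

        diff = means[1] - means[0]
        w = np.linalg.solve(pooled, diff)
        self.means_ = means
        self.covariance_ = pooled
        self.priors_ = priors
        self.coef_ = w
        # midpoint of projected class means, shifted by the log prior ratio
        self.threshold_ = float(w @ (means[0] + means[1]) / 2.0 - np.log(priors[1] / priors[0]))
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        """Gender score wᵀx − threshold; > 0 classifies as the positive class."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ - self.threshold_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.classes_[1], self.classes_[0])


def _as_matrix(cohort: pd.DataFrame, features, label_column: str):
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks feature column(s): {missing}")
    if label_column not in cohort.columns:
        raise KeyError(f"cohort lacks label column {label_column!r}")
    X = cohort[list(features)].to_numpy(dtype=float)
    y = cohort[label_column].to_numpy()
    return X, y


def fit_lda(cohort: pd.DataFrame, features, label_column: str = "sex", **kwargs) -> GenderLDA:
    """Fit a :class:`GenderLDA` on named cohort columns."""
    X, y = _as_matrix(cohort, features, label_column)
    model = GenderLDA(**kwargs).fit(X, y)
    model.feature_names_ = list(features)
    return model


def gender_score(model: GenderLDA, x) -> float:
    """Score one subject given as a mapping, DistanceVector or array.

    For named input the model must have been fitted through
    :func:`fit_lda`; a missing feature raises ``KeyError`` naming it.
    """
    values = x
    if not isinstance(values, dict) and isinstance(getattr(x, "values", None), dict):
        values = x.values  # DistanceVector carries a .values dict
    if isinstance(values, dict):
        names = getattr(model, "feature_names_", None)
        if names is None:
            raise ValueError("model has no feature names; pass an array instead")
        missing = [f for f in names if f not in values]
        if missing:
            raise KeyError(f"subject is missing feature(s): {missing}")
        row = np.array([values[f] for f in names], dtype=float)
    else:
        row = np.asarray(values, dtype=float)
    return float(model.decision_function(row.reshape(1, -1))[0])


def per_class_accuracy(y_true, y_pred, classes) -> dict[str, float]:
    """Per-class accuracy in percent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return {
        str(c): 100.0 * float(np.mean(y_pred[y_true == c] == c)) for c in classes
    }


def cross_validate(
    cohort: pd.DataFrame,
    features,
    label_column: str = "sex",
    folds: int = 10,
    seed: int = DEFAULT_CV_SEED,
    **kwargs,
) -> dict:
    """Stratified k-fold cross-validation of :class:`GenderLDA`.

    Folds are assigned by a seeded stratified shuffle; each sample is
    predicted exactly once by a model that never saw it. Per-class
    accuracies are pooled over all out-of-fold predictions (per-fold
    averages are also reported).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = _as_matrix(cohort, features, label_column)
    classes, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_overall = []
    for train, test in skf.split(X, y):
        model = GenderLDA(**kwargs).fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
        fold_overall.append(float(np.mean(y_pred[test] == y[test])))
    per_class = per_class_accuracy(y, y_pred, classes)
    return {
        "per_class_accuracy": per_class,
        "overall_accuracy": 100.0 * float(np.mean(y_pred == y)),
        "fold_accuracies": [100.0 * a for a in fold_overall],
        "mean_fold_accuracy": 100.0 * float(np.mean(fold_overall)),
        "folds": folds,
        "seed": seed,
        "features": list(features),
    }
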