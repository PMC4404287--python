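"""Two-group discriminant function analysis (canonical discriminant).

Canonical weights come from the leading eigenvector of W⁻¹B (W = pooled
within-group scatter, B = between-group scatter); standardized
coefficients rescale each raw weight by the pooled within-group SD,
√(W_ii/(n−g)), so they express a variable's contribution per SD and are
invariant to per-feature unit changes. Group separation is summarised by
Wilks' Λ = det(W)/det(W+B) with Bartlett's χ² approximation
−(n − 1 − (p+g)/2)·ln Λ on p·(g−1) degrees of freedom. Classification
uses the Fisher rule (nearest projected centroid, equal priors by
default) with resubstitution and leave-one-out (jackknife) accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


@dataclass
class DFAResult:
    """Summary of a fitted two-group discriminant function analysis."""

    features: list[str]
    raw_coefficients: dict[str, float]
    standardized_coefficients: dict[str, float]
    wilks_lambda: float
    chi_square: float
    chi_df: int
    p: float
    classification_accuracy: float  # resubstitution, percent
    cv_accuracy: float | None  # leave-one-out, percent
    group_accuracy: dict[str, float] = field(default_factory=dict)
    cv_group_accuracy: dict[str, float] = field(default_factory=dict)
    groups: list[str] = field(default_factory=list)

    @property
    def significant_predictors(self) -> list[str]:
        return flag_significant_predictors(self)

    def as_dict(self) -> dict:
        return {
            "features": self.features,
            "raw_coefficients": self.raw_coefficients,
            "standardized_coefficients": self.standardized_coefficients,
            "wilks_lambda": self.wilks_lambda,
            "chi_square": self.chi_square,
            "chi_df": self.chi_df,
            "p": self.p,
            "classification_accuracy": self.classification_accuracy,
            "cv_accuracy": self.cv_accuracy,
            "group_accuracy": self.group_accuracy,
            "cv_group_accuracy": self.cv_group_accuracy,
            "groups": self.groups,
            "significant_predictors": self.significant_predictors,
        }


class DiscriminantFunctionAnalysis(BaseEstimator, ClassifierMixin):
    """Two-group canonical DFA as an sklearn-style classifier.

    Parameters
    ----------
    priors : "equal" or "proportional"
        Priors for the Fisher classification rule.
    positive_class : optional label
        Group whose centroid projects positive on the canonical axis
        (resolves the eigenvector sign ambiguity); defaults to the
        lexicographically last group label.
    compute_loo : bool
        Refit n times for leave-one-out accuracy during ``fit``. Turn off
        for large simulation studies where only Λ/χ² are needed.

    Attributes
    ----------
    classes_, coef_ (raw canonical weights), std_coef_, wilks_lambda_,
    chi_square_, chi_df_, p_value_, accuracy_, loo_accuracy_.
    """

    def __init__(self, priors: str = "equal", positive_class=None, compute_loo: bool = True):
        self.priors = priors
        self.positive_class = positive_class
        self.compute_loo = compute_loo

    def _scatter(self, X, y, classes):
        grand = X.mean(axis=0)
        p = X.shape[1]
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        for c in classes:
            xc = X[y == c]
            mu = xc.mean(axis=0)
            d = xc - mu
            W += d.T @ d
            B += len(xc) * np.outer(mu - grand, mu - grand)
        return W, B

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("two-group DFA needs exactly 2 groups")
        n, p = X.shape
        g = 2
        if counts.min() <= p:
            raise ValueError(
                f"smallest group (n={counts.min()}) must exceed the number of "
                f"features ({p}); drop features or regularise"
            )
        if self.positive_class is not None:
            if self.positive_class not in classes:
                raise ValueError(f"positive_class {self.positive_class!r} not in labels")
            classes = np.array(
                [classes[classes != self.positive_class][0], self.positive_class]
            )
        self.classes_ = classes

        W, B = self._scatter(X, y, classes)
        evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
        lead = int(np.argmax(evals.real))
        v = evecs[:, lead].real

        # canonical normalisation: discriminant scores have unit pooled
        # within-group variance (makes raw/standardized weights well defined)
        v = v / np.sqrt(v @ (W / (n - g)) @ v)
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        if (means[1] - means[0]) @ v < 0:  # positive class projects positive
            v = -v

        self.coef_ = v
        self.std_coef_ = v * np.sqrt(np.diag(W) / (n - g))
        self.means_ = means
        self.centroids_ = means @ v

        T = W + B
        self.wilks_lambda_ = float(np.linalg.det(W) / np.linalg.det(T))
        self.chi_square_ = float(-(n - 1 - (p + g) / 2.0) * np.log(self.wilks_lambda_))
        self.chi_df_ = p * (g - 1)
        self.p_value_ = float(sps.chi2.sf(self.chi_square_, self.chi_df_))

        if self.priors == "equal":
            self.priors_ = np.array([0.5, 0.5])
        elif self.priors == "proportional":
            order = [int(np.flatnonzero(np.unique(y) == c)[0]) for c in classes]
            self.priors_ = counts[order] / n
        else:
            raise ValueError("priors must be 'equal' or 'proportional'")
        # Fisher rule threshold on the canonical axis: midpoint of projected
        # centroids shifted by the log prior ratio over the projected
        # within-group variance.
        s2 = float(v @ (W / (n - g)) @ v)
        self.threshold_ = float(
            self.centroids_.mean()
            - s2 * np.log(self.priors_[1] / self.priors_[0]) / (self.centroids_[1] - self.centroids_[0])
        )
        self.n_features_in_ = p

        pred = self.predict(X)
        self.accuracy_ = 100.0 * float(np.mean(pred == y))
        self.group_accuracy_ = {
            str(c): 100.0 * float(np.mean(pred[y == c] == c)) for c in classes
        }
        if self.compute_loo:
            loo_pred = np.empty_like(y)
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                sub = DiscriminantFunctionAnalysis(
                    priors=self.priors,
                    positive_class=self.positive_class,
                    compute_loo=False,
                ).fit(X[mask], y[mask])
                loo_pred[i] = sub.predict(X[i : i + 1])[0]
            self.loo_accuracy_ = 100.0 * float(np.mean(loo_pred == y))
            self.loo_group_accuracy_ = {
                str(c): 100.0 * float(np.mean(loo_pred[y == c] == c)) for c in classes
            }
        else:
            self.loo_accuracy_ = None
            self.loo_group_accuracy_ = {}
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ - self.threshold_

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.classes_[1], self.classes_[0])

    def result_(self, features=None) -> DFAResult:
        check_is_fitted(self, "coef_")
        names = (
            list(features)
            if features is not None
            else [f"x{i}" for i in range(self.n_features_in_)]
        )
        return DFAResult(
            features=names,
            raw_coefficients={f: float(c) for f, c in zip(names, self.coef_)},
            standardized_coefficients={f: float(c) for f, c in zip(names, self.std_coef_)},
            wilks_lambda=self.wilks_lambda_,
            chi_square=self.chi_square_,
            chi_df=self.chi_df_,
            p=self.p_value_,
            classification_accuracy=self.accuracy_,
            cv_accuracy=self.loo_accuracy_,
            group_accuracy=self.group_accuracy_,
            cv_group_accuracy=self.loo_group_accuracy_,
            groups=[str(c) for c in self.classes_],
        )


def fit_dfa(
    cohort: pd.DataFrame,
    features,
    group_column: str = "group",
    priors: str = "equal",
    positive_class="high_AQ",
    compute_loo: bool = True,
) -> DFAResult:
    """Fit a two-group DFA on named cohort columns and summarise it."""
    feats = list(features)
    missing = [f for f in feats if f not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks feature column(s): {missing}")
    X = cohort[feats].to_numpy(dtype=float)
    y = cohort[group_column].to_numpy()
    if positive_class is not None and positive_class not in set(y):
        positive_class = None
    model = DiscriminantFunctionAnalysis(
        priors=priors, positive_class=positive_class, compute_loo=compute_loo
    ).fit(X, y)
    return model.result_(features=feats)


def flag_significant_predictors(result: DFAResult, threshold: float = 0.30) -> list[str]:
    """Features whose |standardized coefficient| strictly exceeds the
    threshold (0.30 by convention); signs are preserved in the report."""
    return [
        f
        for f in result.features
        if abs(result.standardized_coefficients[f]) > threshold
    ]
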