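"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Relevance and redundancy are plug-in mutual informations (bits) computed
on equal-frequency-discretised features. The greedy forward step adds the
feature maximising, in the MID (difference) variant,

    I(x; class) − (1/|S|) Σ_{x_j in S} I(x; x_j)

over the already-selected set S; the MIQ (quotient) variant divides
instead. Ties break lexicographically by feature name so the ranking is
deterministic. Equal-frequency binning makes the ranking invariant to any
monotone rescaling of a feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .lda import DEFAULT_CV_SEED, cross_validate


def _discretise(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency discretisation to at most ``bins`` levels."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete sequences."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (pa @ pb)[mask])))


def mutual_information(x, labels, bins: int = 8) -> float:
    """MI (bits) between a numeric feature and class labels.

    The feature is equal-frequency binned into ``bins`` levels and the MI
    estimated from the joint histogram. Bounded by log2(bins) and by the
    label entropy. A constant feature carries no information (warned).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    if np.ptp(x) == 0:
        warnings.warn("constant feature has zero mutual information", stacklevel=2)
        return 0.0
    return _mi_discrete(_discretise(x, bins), labels)


@dataclass
class MRMRResult:
    """Ordered ranking with per-step criterion values and relevances."""

    ranking: list[str]
    scores: list[float]
    relevance: dict[str, float]
    params: dict = field(default_factory=dict)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy mRMR feature ranker/selector (sklearn transformer).

    Parameters
    ----------
    k : int or None
        Number of features to keep in ``transform``; None keeps all
        (the full ranking is always computed).
    bins : int
        Equal-frequency discretisation levels for MI estimation.
    variant : "MID" or "MIQ"
        Difference (default) or quotient redundancy penalty.
    """

    def __init__(self, k: int | None = None, bins: int = 8, variant: str = "MID"):
        self.k = k
        self.bins = bins
        self.variant = variant

    def fit(self, X, y):
        if self.variant not in ("MID", "MIQ"):
            raise ValueError("variant must be 'MID' or 'MIQ'")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if hasattr(X, "columns"):
            names = [str(c) for c in X.columns]
        else:
            names = [f"x{i}" for i in range(np.shape(X)[1])]
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.k is not None and self.k > p:
            raise ValueError(f"k={self.k} exceeds feature count {p}")

        disc = np.column_stack([_discretise(X[:, j], self.bins) for j in range(p)])
        relevance = np.array([_mi_discrete(disc[:, j], y) for j in range(p)])
        # pairwise feature MI, filled lazily
        pair_mi = np.full((p, p), np.nan)

        def redundancy(j: int, selected: list[int]) -> float:
            total = 0.0
            for s in selected:
                if np.isnan(pair_mi[j, s]):
                    pair_mi[j, s] = pair_mi[s, j] = _mi_discrete(disc[:, j], disc[:, s])
                total += pair_mi[j, s]
            return total / len(selected)

        order = sorted(range(p), key=lambda j: names[j])  # lexicographic tie-break
        selected: list[int] = []
        scores: list[float] = []
        remaining = set(range(p))
        while remaining:
            best_j, best_score = None, -np.inf
            for j in order:
                if j not in remaining:
                    continue
                if not selected:
                    score = relevance[j]
                elif self.variant == "MID":
                    score = relevance[j] - redundancy(j, selected)
                else:
                    score = relevance[j] / max(redundancy(j, selected), 1e-12)
                if score > best_score + 1e-12:  # strict improvement; earlier name wins ties
                    best_j, best_score = j, score
            selected.append(best_j)
            scores.append(float(best_score))
            remaining.discard(best_j)

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.ranking_ = [names[j] for j in selected]
        self.ranking_idx_ = np.asarray(selected)
        self.scores_ = scores
        self.relevance_ = {names[j]: float(relevance[j]) for j in range(p)}
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_idx_")
        k = self.n_features_in_ if self.k is None else self.k
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_idx_[:k]] = True
        return mask

    def result_(self) -> MRMRResult:
        check_is_fitted(self, "ranking_")
        return MRMRResult(
            ranking=list(self.ranking_),
            scores=list(self.scores_),
            relevance=dict(self.relevance_),
            params={"bins": self.bins, "variant": self.variant},
        )


def mrmr_rank(
    cohort: pd.DataFrame,
    label_column: str = "sex",
    k: int | None = None,
    bins: int = 8,
    variant: str = "MID",
    features=None,
) -> MRMRResult:
    """Rank cohort feature columns by greedy mRMR against a label column."""
    from .landmarks import feature_columns

    feats = list(features) if features is not None else feature_columns(cohort)
    sel = MRMRSelector(k=k, bins=bins, variant=variant)
    sel.fit(cohort[feats], cohort[label_column].to_numpy())
    res = sel.result_()
    if k is not None:
        res.ranking = res.ranking[:k]
        res.scores = res.scores[:k]
    return res


def select_optimal_subset(
    cohort: pd.DataFrame,
    label_column: str = "sex",
    ranking: MRMRResult | None = None,
    folds: int = 10,
    seed: int = DEFAULT_CV_SEED,
    bins: int = 8,
    variant: str = "MID",
) -> dict:
    """Pick the ranking prefix with the best cross-validated LDA accuracy.

    Nested prefixes of the mRMR ranking are evaluated with stratified
    k-fold LDA; the prefix maximising mean per-class accuracy wins, with
    ties going to the smaller subset (the full 2^p search is intractable
    and standard mRMR practice searches prefixes).
    """
    if ranking is None:
        ranking = mrmr_rank(cohort, label_column, bins=bins, variant=variant)
    best = None
    evaluations = []
    for size in range(1, len(ranking.ranking) + 1):
        feats = ranking.ranking[:size]
        cv = cross_validate(cohort, feats, label_column, folds=folds, seed=seed)
        mean_pc = float(np.mean(list(cv["per_class_accuracy"].values())))
        evaluations.append(
            {"size": size, "features": feats, "mean_per_class_accuracy": mean_pc, "cv": cv}
        )
        if best is None or mean_pc > best["mean_per_class_accuracy"] + 1e-12:
            best = evaluations[-1]
    return {
        "features": best["features"],
        "per_class_accuracy": best["cv"]["per_class_accuracy"],
        "mean_per_class_accuracy": best["mean_per_class_accuracy"],
        "size": best["size"],
        "evaluations": evaluations,
        "ranking": ranking,
    }
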