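"""Pooled two-sample t-tests, r² effect sizes, dimorphism-direction calls.

The pooled (equal-variance) form is used throughout — it is the form whose
degrees of freedom equal n₁+n₂−2, matching the published dfs (206, 56, 52)
— and the effect size is r² = t²/(t²+df), the proportion of variance in
the feature explained by group membership. Tests run either on raw cohort
columns or directly from printed summary moments, and the two routes agree
exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmarks import feature_columns


@dataclass
class TTestResult:
    feature: str
    t: float
    df: int
    p: float
    r2: float
    m1: float
    sd1: float
    n1: int
    m2: float
    sd2: float
    n2: int
    group1: str = "group1"
    group2: str = "group2"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


Direction = Literal["less_sex_typical", "more_sex_typical", "null"]


@dataclass
class DimorphismCall:
    """Directional interpretation of a high-vs-low trait difference.

    ``direction`` says whether the high-trait group's feature shifted away
    from (``less_sex_typical``) or beyond (``more_sex_typical``) its sex's
    typical value, relative to the male-vs-female dimorphism reference;
    non-significant differences are ``null``.
    """

    feature: str
    sex: str
    direction: Direction
    high_minus_low: float
    male_minus_female: float
    p: float


def summary_t_test(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
    feature: str = "", group1: str = "group1", group2: str = "group2",
) -> TTestResult:
    """Pooled two-sample t-test from summary statistics (means, SDs, ns)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    r2 = t**2 / (t**2 + df)
    return TTestResult(feature, float(t), df, float(p), float(r2),
                       m1, sd1, n1, m2, sd2, n2, group1, group2)


def cohort_t_tests(
    cohort: pd.DataFrame,
    features=None,
    grouping: str = "group",
    group_order: tuple[str, str] | None = None,
) -> list[TTestResult]:
    """Per-feature pooled t-tests between the two levels of a group column.

    Results are identical to :func:`summary_t_test` applied to each
    feature's per-group sample moments (ddof=1 SDs).
    """
    if grouping not in cohort.columns:
        raise KeyError(f"cohort lacks grouping column {grouping!r}")
    levels = group_order if group_order is not None else tuple(sorted(cohort[grouping].unique()))
    if len(set(cohort[grouping])) != 2 or len(levels) != 2:
        raise ValueError(f"grouping column {grouping!r} must have exactly 2 levels")
    g1 = cohort[cohort[grouping] == levels[0]]
    g2 = cohort[cohort[grouping] == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need n >= 2")
    feats = list(features) if features is not None else feature_columns(cohort)
    out = []
    for f in feats:
        out.append(
            summary_t_test(
                float(g1[f].mean()), float(g1[f].std(ddof=1)), len(g1),
                float(g2[f].mean()), float(g2[f].std(ddof=1)), len(g2),
                feature=f, group1=str(levels[0]), group2=str(levels[1]),
            )
        )
    return out


def call_dimorphism_direction(
    sex_reference: TTestResult,
    trait_result: TTestResult,
    sex: str,
    alpha: float = 0.05,
) -> DimorphismCall:
    """Classify a high-vs-low trait difference against the sex dimorphism.

    ``sex_reference`` is the male-vs-female comparison (male first) for the
    same feature; ``trait_result`` the high-vs-low comparison (high first).
    For males on a male-larger feature, significantly smaller high-group
    values are less sex-typical (less masculinised). For females on a
    male-larger feature, significantly larger high-group values are less
    sex-typical (less feminised) and significantly smaller ones are more
    sex-typical. Non-significant differences are null calls.
    """
    if sex_reference.feature != trait_result.feature:
        raise ValueError(
            f"feature mismatch: {sex_reference.feature!r} vs {trait_result.feature!r}"
        )
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    dimorphism = sex_reference.m1 - sex_reference.m2  # male - female
    diff = trait_result.m1 - trait_result.m2  # high - low
    if trait_result.p >= alpha:
        direction: Direction = "null"
    else:
        # toward_male: high group shifted in the male-typical direction
        toward_male = diff * dimorphism > 0
        if sex == "male":
            direction = "more_sex_typical" if toward_male else "less_sex_typical"
        else:
            direction = "less_sex_typical" if toward_male else "more_sex_typical"
    return DimorphismCall(
        feature=trait_result.feature,
        sex=sex,
        direction=direction,
        high_minus_low=float(diff),
        male_minus_female=float(dimorphism),
        p=trait_result.p,
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (reported alongside raw p; the
    original analyses applied no correction)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
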