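"""End-to-end orchestration of the two analyses.

Study 1: on a sexed cohort, rank all distances by mRMR, select the
optimal subset by tenfold cross-validated LDA, and report per-sex
descriptives plus per-feature male-vs-female t-tests.

Study 2: within each sex, compare high- and low-trait groups on the
dimorphic distances (pooled t-tests with r², facial-area control),
classify each significant difference as more/less sex-typical against
the study-1 dimorphism reference, and run a discriminant function
analysis on the significant features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dfa import fit_dfa
from .geometry import SELECTED_FEATURES
from .landmarks import feature_columns, read_cohort
from .lda import DEFAULT_CV_SEED, cross_validate
from .selection import mrmr_rank, select_optimal_subset
from .simulate import builtin_specs, generate_distance_cohort
from .stats import call_dimorphism_direction, cohort_t_tests, holm_adjust, summary_t_test


@dataclass
class PipelineConfig:
    """Configuration for the two-study pipeline."""

    study1_cohort: str | None = None  # path, or None for the builtin preset
    study2_male_cohort: str | None = None
    study2_female_cohort: str | None = None
    seed: int = 7
    n_scale: float = 1.0
    rho: float = 0.3
    bins: int = 8
    mrmr_variant: str = "MID"
    folds: int = 10
    cv_seed: int = DEFAULT_CV_SEED
    alpha: float = 0.05
    dfa_priors: str = "equal"
    features: list[str] | None = None  # override study-2 feature list
    out_dir: str | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }


def _load_or_simulate(config: PipelineConfig, which: str) -> pd.DataFrame:
    path = getattr(config, f"{which.replace('-', '_')}_cohort")
    if path is not None:
        return read_cohort(path)
    spec = builtin_specs(rho=config.rho)[which]
    return generate_distance_cohort(spec, seed=config.seed, n_scale=config.n_scale)


def run_study1(config: PipelineConfig) -> dict:
    """Sex-dimorphism analysis: descriptives, mRMR ranking, subset, CV, t-tests."""
    cohort = _load_or_simulate(config, "study1")
    if "sex" not in cohort.columns:
        raise ValueError("study-1 cohort needs a sex column")
    feats = feature_columns(cohort)
    if len(feats) < 6:
        raise ValueError("study-1 cohort needs at least 6 feature columns")

    descriptives = {
        sex: {
            f: {
                "mean": float(cohort.loc[cohort.sex == sex, f].mean()),
                "sd": float(cohort.loc[cohort.sex == sex, f].std(ddof=1)),
                "n": int((cohort.sex == sex).sum()),
            }
            for f in feats
        }
        for sex in sorted(cohort["sex"].unique())
    }

    ranking = mrmr_rank(cohort, "sex", bins=config.bins, variant=config.mrmr_variant)
    selection = select_optimal_subset(
        cohort, "sex", ranking, folds=config.folds, seed=config.cv_seed
    )
    # male-vs-female tests on the selected features, male group first
    tests = cohort_t_tests(
        cohort, selection["features"], grouping="sex", group_order=("male", "female")
    )
    p_holm = holm_adjust([t.p for t in tests])
    return {
        "study": "study1",
        **_provenance(config),
        "n_subjects": int(len(cohort)),
        "descriptives": descriptives,
        "mrmr_ranking": ranking.ranking,
        "mrmr_relevance": ranking.relevance,
        "selected_features": selection["features"],
        "per_class_accuracy": selection["per_class_accuracy"],
        "mean_per_class_accuracy": selection["mean_per_class_accuracy"],
        "t_tests": [
            {**t.as_dict(), "p_holm": float(ph)} for t, ph in zip(tests, p_holm)
        ],
    }


def run_study2(
    config: PipelineConfig,
    selected_features=None,
    sex_reference: dict | None = None,
) -> dict:
    """High- vs low-trait comparison within each sex, plus DFA.

    ``selected_features`` defaults to the config override or the six
    canonical dimorphic distances. ``sex_reference`` maps feature name to
    the study-1 male-vs-female TTestResult; when absent it is computed
    from the printed study-1 summary moments via the builtin preset.
    """
    feats = list(
        selected_features
        if selected_features is not None
        else (config.features or SELECTED_FEATURES)
    )
    if sex_reference is None:
        spec = builtin_specs()["study1"]
        male, female = spec.groups[0], spec.groups[1]
        sex_reference = {
            f: summary_t_test(
                male.means[f], male.sds[f], male.n,
                female.means[f], female.sds[f], female.n,
                feature=f, group1="male", group2="female",
            )
            for f in feats
            if f in male.means
        }

    report = {"study": "study2", **_provenance(config), "per_sex": {}}
    for sex, which in (("male", "study2-male"), ("female", "study2-female")):
        cohort = _load_or_simulate(config, which)
        if "group" not in cohort.columns:
            raise ValueError(f"{which} cohort needs a group column")
        cohort = cohort[cohort.sex == sex]
        usable = [f for f in feats if f in cohort.columns]
        # high-AQ first so positive differences mean "high group larger"
        tests = cohort_t_tests(
            cohort, usable, grouping="group", group_order=("high_AQ", "low_AQ")
        )
        calls = [
            call_dimorphism_direction(sex_reference[t.feature], t, sex, alpha=config.alpha)
            for t in tests
            if t.feature in sex_reference
        ]
        area_test = None
        if "facial_area" in cohort.columns:
            area_test = cohort_t_tests(
                cohort, ["facial_area"], grouping="group",
                group_order=("high_AQ", "low_AQ"),
            )[0].as_dict()
        significant = [t.feature for t in tests if t.p < config.alpha]
        dfa_report = None
        if len(significant) >= 1:
            smallest = int(cohort.groupby("group").size().min())
            if smallest > len(significant):
                dfa_report = fit_dfa(
                    cohort, significant, "group",
                    priors=config.dfa_priors, positive_class="high_AQ",
                ).as_dict()
        report["per_sex"][sex] = {
            "n_per_group": {k: int(v) for k, v in cohort.groupby("group").size().items()},
            "t_tests": [t.as_dict() for t in tests],
            "facial_area_control": area_test,
            "dimorphism_calls": [asdict(c) for c in calls],
            "significant_features": significant,
            "dfa": dfa_report,
        }
    return report


def _write_reports(report: dict, out_dir: Path, name: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp = out_dir / f".{name}.json.tmp"
    tmp.write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    tmp.replace(out_dir / f"{name}.json")  # atomic: no partial reports
    (out_dir / f"{name}.md").write_text(_markdown_report(report))


def _markdown_report(report: dict) -> str:
    lines = [f"# {report['study']} report", ""]
    lines.append(f"- version: {report['version']}")
    lines.append(f"- seed: {report['seed']}  config: {report['config_hash']}")
    if report["study"] == "study1":
        lines.append(f"- subjects: {report['n_subjects']}")
        lines.append(f"- selected features: {', '.join(report['selected_features'])}")
        acc = report["per_class_accuracy"]
        lines.append(
            "- tenfold LDA accuracy: "
            + ", ".join(f"{k} {v:.2f}%" for k, v in acc.items())
        )
        lines.append("")
        lines.append("| feature | t | df | p | r² |")
        lines.append("|---|---|---|---|---|")
        for t in report["t_tests"]:
            lines.append(
                f"| {t['feature']} | {t['t']:.2f} | {t['df']} | {t['p']:.3g} | {t['r2']:.2f} |"
            )
    else:
        for sex, block in report["per_sex"].items():
            lines.append(f"\n## {sex}")
            lines.append(f"- groups: {block['n_per_group']}")
            lines.append("\n| feature | t(high−low) | p | r² | call |")
            lines.append("|---|---|---|---|---|")
            calls = {c["feature"]: c["direction"] for c in block["dimorphism_calls"]}
            for t in block["t_tests"]:
                lines.append(
                    f"| {t['feature']} | {t['t']:.2f} | {t['p']:.3g} | {t['r2']:.2f} "
                    f"| {calls.get(t['feature'], '-')} |"
                )
            if block["dfa"] is not None:
                d = block["dfa"]
                lines.append(
                    f"\nDFA: Λ={d['wilks_lambda']:.3f}, χ²({d['chi_df']})={d['chi_square']:.1f}, "
                    f"p={d['p']:.3g}; accuracy {d['classification_accuracy']:.1f}% "
                    f"(LOO {d['cv_accuracy']:.1f}%)"
                )
                lines.append("\n| feature | standardized coefficient |")
                lines.append("|---|---|")
                for f, c in d["standardized_coefficients"].items():
                    lines.append(f"| {f} | {c:.2f} |")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run both studies; study-2 features come from study-1 selection."""
    s1 = run_study1(config)
    s2 = run_study2(
        config,
        selected_features=(config.features or s1["selected_features"]),
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_reports(s1, out, "study1")
        _write_reports(s2, out, "study2")
    return {"study1": s1, "study2": s2}
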