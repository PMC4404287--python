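"""Two-class LDA: closed forms, oracle equivalence, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from facedim import GenderLDA, cross_validate, fit_lda, gender_score
from facedim.geometry import SELECTED_FEATURES


def _spherical_classes(rng, n=200, sep=2.0, p=2):
    X = rng.standard_normal((2 * n, p))
    X[:n, 0] -= sep / 2
    X[n:, 0] += sep / 2
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestFit:
    def test_two_spherical_classes_closed_form(self, rng):
        """Unit-variance classes at (±1, 0): w ∝ (1, 0), threshold 0."""
        X, y = _spherical_classes(rng, n=20000, sep=2.0)
        model = GenderLDA().fit(X, y)
        w = model.coef_ / np.linalg.norm(model.coef_)
        assert abs(w[0]) == pytest.approx(1.0, abs=0.03)
        # threshold in score units: scores of the two class means are symmetric
        s = model.decision_function(model.means_)
        assert s[0] == pytest.approx(-s[1], rel=0.05)

    def test_univariate_threshold_closed_form(self, rng):
        """1-D boundary = midpoint + σ²·log(π₀/π₁)/(μ₁−μ₀)."""
        mu0, mu1, sigma = 2.0, 5.0, 1.3
        X = np.concatenate([rng.normal(mu0, sigma, 4000), rng.normal(mu1, sigma, 2000)])
        y = np.array(["a"] * 4000 + ["b"] * 2000)
        model = GenderLDA(priors="proportional").fit(X.reshape(-1, 1), y)
        boundary = model.threshold_ / model.coef_[0]  # x where score = 0
        m0h, m1h = X[:4000].mean(), X[4000:].mean()
        s2 = (X[:4000].var(ddof=1) * 3999 + X[4000:].var(ddof=1) * 1999) / 5998
        expected = (m0h + m1h) / 2 - s2 * np.log((2000 / 6000) / (4000 / 6000)) / (m1h - m0h)
        assert boundary == pytest.approx(expected, rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            GenderLDA().fit(np.random.default_rng(0).standard_normal((10, 2)), ["a"] * 10)

    def test_singular_covariance_ridged_with_warning(self, rng):
        X = np.repeat(rng.standard_normal((40, 1)), 2, axis=1)  # rank-1
        X[:20, 0] += 3
        y = np.array(["a"] * 20 + ["b"] * 20)
        with pytest.warns(UserWarning, match="ridge"):
            model = GenderLDA().fit(X, y)
        assert np.all(np.isfinite(model.coef_))

    def test_positive_class_is_male(self, study1_cohort):
        model = fit_lda(study1_cohort, list(SELECTED_FEATURES), "sex")
        assert model.classes_[1] == "male"
        # male centroid scores positive, female negative
        assert model.decision_function(model.means_[1:2])[0] > 0
        assert model.decision_function(model.means_[0:1])[0] < 0

    def test_sklearn_oracle_equivalence(self, study1_cohort):
        """Predictions match sklearn's eigen-solver LDA on the same data."""
        X = study1_cohort[list(SELECTED_FEATURES)].to_numpy()
        y = study1_cohort["sex"].to_numpy()
        ours = GenderLDA(priors="proportional").fit(X, y).predict(X)
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, y).predict(X)
        assert np.array_equal(ours, ref)

    def test_affine_invariance(self, study1_cohort, rng):
        """One common invertible affine map leaves predictions unchanged."""
        X = study1_cohort[list(SELECTED_FEATURES)].to_numpy()
        y = study1_cohort["sex"].to_numpy()
        A = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        b = rng.uniform(-10, 10, 6)
        base = GenderLDA().fit(X, y).predict(X)
        mapped = GenderLDA().fit(X @ A.T + b, y).predict(X @ A.T + b)
        assert np.mean(base == mapped) > 0.999


class TestGenderScore:
    def test_training_centroids_and_midpoint(self, study1_cohort):
        model = fit_lda(study1_cohort, list(SELECTED_FEATURES), "sex")
        male_centroid = dict(zip(model.feature_names_, model.means_[1]))
        assert gender_score(model, male_centroid) > 0
        midpoint = dict(zip(model.feature_names_, model.means_.mean(axis=0)))
        assert gender_score(model, midpoint) == pytest.approx(0.0, abs=1e-9)

    def test_missing_feature_named(self, study1_cohort):
        model = fit_lda(study1_cohort, list(SELECTED_FEATURES), "sex")
        with pytest.raises(KeyError, match="nose_width"):
            gender_score(model, {f: 10.0 for f in SELECTED_FEATURES if f != "nose_width"})

    def test_affine_in_x(self, study1_cohort):
        """score is affine: score(mid(a,b)) == mean(score(a), score(b))."""
        model = fit_lda(study1_cohort, list(SELECTED_FEATURES), "sex")
        a = {f: 10.0 for f in SELECTED_FEATURES}
        b = {f: 30.0 for f in SELECTED_FEATURES}
        mid = {f: 20.0 for f in SELECTED_FEATURES}
        sa, sb, sm = (gender_score(model, v) for v in (a, b, mid))
        assert sm == pytest.approx((sa + sb) / 2, rel=1e-9)


class TestCrossValidate:
    def _cohort(self, X, y):
        t = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        t.insert(0, "subject_id", [f"s{i}" for i in range(len(t))])
        t.insert(1, "sex", y)
        return t

    def test_perfect_separation_any_seed(self, rng):
        X, y = _spherical_classes(rng, n=50, sep=30.0)
        cohort = self._cohort(X, np.where(y == "a", "female", "male"))
        for seed in (0, 1, 99):
            cv = cross_validate(cohort, ["f0", "f1"], "sex", seed=seed)
            assert cv["overall_accuracy"] == 100.0
            assert all(v == 100.0 for v in cv["per_class_accuracy"].values())

    def test_deterministic_under_seed(self, study1_cohort):
        a = cross_validate(study1_cohort, list(SELECTED_FEATURES), "sex", seed=5)
        b = cross_validate(study1_cohort, list(SELECTED_FEATURES), "sex", seed=5)
        assert a == b

    def test_each_sample_predicted_once(self, study1_cohort):
        cv = cross_validate(study1_cohort, list(SELECTED_FEATURES), "sex")
        assert cv["folds"] == 10
        assert len(cv["fold_accuracies"]) == 10

    def test_too_many_folds_rejected(self, study1_cohort):
        small = study1_cohort.groupby("sex").head(5)  # 5 per class < 10 folds
        with pytest.raises(ValueError, match="folds"):
            cross_validate(small, list(SELECTED_FEATURES), "sex", folds=10)

    def test_accuracy_monotone_in_dimorphic_features(self, study1_large):
        """Adding true dimorphic features (by effect size) raises accuracy."""
        ordered = ["forehead_width", "nose_width", "nasal_bridge_length",
                   "nasal_tip_protrusion", "outer_canthal_width", "philtrum_length"]
        accs = [
            cross_validate(study1_large, ordered[:k], "sex")["overall_accuracy"]
            for k in (1, 3, 6)
        ]
        assert accs[0] < accs[1] < accs[2]
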