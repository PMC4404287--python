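"""Synthetic cohort generator: presets, determinism, parameter recovery,
landmark closure and the icosphere oracle."""

import numpy as np
import pandas as pd
import pytest

from facedim import (
    GroupSpec,
    InfeasibleDistanceError,
    builtin_specs,
    compute_distances,
    generate_distance_cohort,
    generate_icosphere,
    generate_landmark_cohort,
    generate_landmarks_for_targets,
    mesh_surface_area,
    template_landmarks,
)
from facedim.geometry import SELECTED_FEATURES
from facedim.simulate import FILLER_FEATURES


class TestPresets:
    def test_study1_printed_parameters(self):
        spec = builtin_specs()["study1"]
        male, female = spec.groups
        assert (male.n, female.n) == (107, 101)
        assert male.means["forehead_width"] == 124.12
        assert male.sds["forehead_width"] == 5.27
        assert female.means["nose_width"] == 29.08
        assert female.sds["philtrum_length"] == 1.94

    def test_study2_printed_parameters(self):
        specs = builtin_specs()
        low_m, high_m = specs["study2-male"].groups
        assert (low_m.n, high_m.n) == (33, 25)
        assert high_m.means["nasal_tip_protrusion"] == 18.65
        low_f, high_f = specs["study2-female"].groups
        assert (low_f.n, high_f.n) == (33, 21)
        assert high_f.means["nose_width"] == 30.38
        assert low_f.means["facial_area"] == 22800.0

    def test_study1_includes_all_23_distances(self):
        spec = builtin_specs()["study1"]
        assert len(spec.groups[0].means) == 23
        # filler features carry no sex signal by construction
        for f, (mean, sd) in FILLER_FEATURES.items():
            assert spec.groups[0].means[f] == spec.groups[1].means[f] == mean

    def test_philtrum_flagged_suspect_in_study2(self):
        assert "philtrum_length" in builtin_specs()["study2-male"].suspect_features


class TestGroupSpec:
    def test_rejects_tiny_group(self):
        with pytest.raises(ValueError, match=">= 2"):
            GroupSpec("male", 1, {"a": 1.0}, {"a": 1.0})

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError, match="positive"):
            GroupSpec("male", 5, {"a": 1.0}, {"a": 0.0})

    def test_rejects_out_of_range_correlation(self):
        with pytest.raises(ValueError, match="correlation"):
            GroupSpec("male", 5, {"a": 1.0}, {"a": 1.0}, correlation=0.95)

    def test_covariance_structure(self):
        g = GroupSpec("male", 5, {"a": 1.0, "b": 2.0}, {"a": 2.0, "b": 3.0}, correlation=0.5)
        np.testing.assert_allclose(g.covariance(), [[4.0, 3.0], [3.0, 9.0]])


class TestDistanceCohort:
    def test_deterministic_under_seed(self):
        spec = builtin_specs()["study1"]
        a = generate_distance_cohort(spec, seed=3)
        b = generate_distance_cohort(spec, seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = generate_distance_cohort(spec, seed=4)
        assert not a.equals(c)

    def test_sample_means_converge(self):
        """Law of large numbers: sample means within 0.5% at ~5000/group."""
        spec = builtin_specs()["study1"]
        table = generate_distance_cohort(spec, seed=7, n_scale=5000 / 104)
        for g in spec.groups:
            sub = table[table.sex == g.sex]
            for f, mu in g.means.items():
                assert sub[f].mean() == pytest.approx(mu, rel=5e-3)

    def test_sample_sds_converge(self):
        spec = builtin_specs()["study1"]
        table = generate_distance_cohort(spec, seed=7, n_scale=5000 / 104)
        male = spec.groups[0]
        sub = table[table.sex == "male"]
        for f, sd in male.sds.items():
            assert sub[f].std(ddof=1) == pytest.approx(sd, rel=0.05)

    @pytest.mark.parametrize("rho", [0.0, 0.5])
    def test_correlation_recovery(self, rho):
        spec = builtin_specs(rho=rho)["study1"]
        table = generate_distance_cohort(spec, seed=7, n_scale=5000 / 104)
        sub = table[table.sex == "male"]
        corr = sub[list(SELECTED_FEATURES)].corr().to_numpy()
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.all(np.abs(off - rho) < 0.1)

    def test_all_values_positive(self, study1_large):
        feats = [c for c in study1_large.columns if c not in ("subject_id", "sex", "group")]
        assert (study1_large[feats].to_numpy() > 0).all()


class TestLandmarkCohort:
    def test_closure_within_tolerance(self):
        """measure(generate(x)) returns the sampled distances (< 0.1 mm)."""
        spec = builtin_specs()["study2-female"]
        faces, table = generate_landmark_cohort(spec, seed=5, n_scale=4 / 54)
        targets = [f for f in SELECTED_FEATURES if f not in spec.suspect_features]
        for face in faces:
            row = table.loc[table.subject_id == face.subject_id].iloc[0]
            dv = compute_distances(face)
            for f in targets:
                assert abs(dv.values[f] - row[f]) < 0.1

    def test_template_fixed_point(self, template):
        targets = compute_distances(template).values
        out = generate_landmarks_for_targets(targets)
        for code in template.points:
            np.testing.assert_allclose(out[code], template[code], atol=1e-6)

    def test_infeasible_targets_raise(self):
        with pytest.raises(InfeasibleDistanceError) as err:
            generate_landmarks_for_targets(
                {"nasal_bridge_length": 0.1, "nose_height": 60.0, "nasal_tip_protrusion": 19.0},
                subject_id="bad",
            )
        assert err.value.subject_id == "bad"
        assert "nose_height" in err.value.offending

    def test_unknown_distance_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_landmarks_for_targets({"skull_diameter": 100.0})


class TestIcosphere:
    def test_icosahedron_closed_form(self):
        """Subdivision 0 is the icosahedron: area 5√3·a² at unit circumradius."""
        mesh = generate_icosphere(1.0, 0)
        a = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))  # edge for unit circumradius
        assert mesh_surface_area(mesh) == pytest.approx(5 * np.sqrt(3) * a**2, rel=1e-12)

    def test_area_monotone_in_subdivisions(self):
        areas = [mesh_surface_area(generate_icosphere(50.0, k)) for k in range(4)]
        limit = 4 * np.pi * 50**2
        assert all(a < b for a, b in zip(areas, areas[1:]))
        assert all(a < limit for a in areas)
        assert areas[-1] == pytest.approx(limit, rel=5e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_icosphere(-1.0, 2)
        with pytest.raises(ValueError):
            generate_icosphere(1.0, 9)
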