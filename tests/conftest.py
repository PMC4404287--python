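import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from facedim import builtin_specs, generate_distance_cohort, template_landmarks


@pytest.fixture(scope="session")
def study1_cohort():
    """Study-1 preset at printed group sizes (107 M / 101 F), seed 7."""
    return generate_distance_cohort(builtin_specs()["study1"], seed=7)


@pytest.fixture(scope="session")
def study1_large():
    """Study-1 preset inflated to ~2000 per sex for convergence checks."""
    return generate_distance_cohort(builtin_specs()["study1"], seed=7, n_scale=2000 / 104)


@pytest.fixture(scope="session")
def study2_male_cohort():
    return generate_distance_cohort(builtin_specs()["study2-male"], seed=11)


@pytest.fixture(scope="session")
def template():
    return template_landmarks()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150415)


def two_gaussian_cohort(rng, n=60, delta=3.0, p=3, labels=("low_AQ", "high_AQ")):
    """Two spherical Gaussian groups separated by ``delta`` along feature 0."""
    a = rng.standard_normal((n, p)) + 10.0
    b = rng.standard_normal((n, p)) + 10.0
    b[:, 0] += delta
    table = pd.DataFrame(
        np.vstack([a, b]), columns=[f"f{i}" for i in range(p)]
    )
    table.insert(0, "subject_id", [f"s{i:04d}" for i in range(2 * n)])
    table.insert(1, "sex", "male")
    table.insert(2, "group", [labels[0]] * n + [labels[1]] * n)
    return table


@pytest.fixture()
def separated_cohort(rng):
    return two_gaussian_cohort(rng, n=40, delta=8.0)
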