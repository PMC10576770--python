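import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from painindex.config import GeneratorConfig
from painindex.features import feature_columns
from painindex.simulate import generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """30 patients x 1 day, default dynamics; shared read-only fixture."""
    return generate_cohort(GeneratorConfig(n_patients=30, duration_min=1440,
                                           seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """200 patients x 2 days at the default configuration."""
    return generate_cohort(GeneratorConfig(n_patients=200, seed=42))


def make_feature_table(n, pos_rate, rng, informative=True, shift=1.5):
    """Synthetic gaussian feature table with the package's schema."""
    cont = [c for c in feature_columns()
            if c not in ("sex", "age_group", "rass")]
    y = (rng.random(n) < pos_rate).astype(int)
    X = rng.standard_normal((n, len(cont)))
    if informative:
        X[y == 1] += shift
    df = pd.DataFrame(X, columns=cont)
    df["sex"] = rng.choice(["male", "female"], n)
    df["age_group"] = rng.choice(["20-44", "45-64", "65+"], n)
    df["rass"] = rng.integers(-5, 5, n)
    df["patient_id"] = [f"P{i // 4:04d}" for i in range(n)]
    df["t_min"] = np.arange(n) * 60 + 60
    df["label"] = y
    return df


@pytest.fixture
def feature_factory():
    return make_feature_table
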