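import numpy as np
import pytest

from imbalmrs import (
    Cohort,
    SmoteConfig,
    generate_cohort,
    load_class_specs,
    load_peak_library,
)


@pytest.fixture(scope="session")
def class_specs():
    """Shipped per-class generator parameters (42/38/10 cohort)."""
    return load_class_specs()


@pytest.fixture(scope="session")
def cohort90(class_specs):
    """One synthetic 90-patient cohort, shared across read-only tests."""
    return generate_cohort(class_specs, seed=11)


@pytest.fixture(scope="session")
def peak_library():
    return load_peak_library()


@pytest.fixture()
def smote_config():
    return SmoteConfig(minority_class="ependymoma", rate=1.0, k=5, seed=3)


def toy_cohort(majority, minority, minority_label="min", majority_label="maj"):
    """1-D (or n-D) two-class cohort from explicit coordinates."""
    majority = np.atleast_2d(np.asarray(majority, dtype=float).reshape(len(majority), -1))
    minority = np.atleast_2d(np.asarray(minority, dtype=float).reshape(len(minority), -1))
    n_maj, n_min = majority.shape[0], minority.shape[0]
    features = np.vstack([majority, minority])
    return Cohort(
        features=features,
        feature_names=[f"f{i}" for i in range(features.shape[1])],
        labels=np.array([majority_label] * n_maj + [minority_label] * n_min, dtype=object),
        sample_ids=np.array([f"S{i:02d}" for i in range(n_maj + n_min)], dtype=object),
    )
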