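import numpy as np
import pandas as pd
import pytest

from fmribucket import (
    BucketConfig,
    FeatureTable,
    SyntheticCohortSpec,
    generate_atlas,
    generate_cohort,
)
from fmribucket.bucket import fast_models


@pytest.fixture(scope="session")
def small_atlas():
    """A 3-region atlas on an 8^3 grid for hand-checkable counting."""
    return generate_atlas(3, (8, 8, 8), seed=0)


@pytest.fixture(scope="session")
def default_atlas():
    """The full-size test atlas: 117 regions on the 24^3 grid."""
    return generate_atlas(117, (24, 24, 24), seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_atlas):
    """Default synthetic cohort (38 CFS / 80 GWI, planted effects), table mode."""
    spec = SyntheticCohortSpec(seed=0)
    return spec, generate_cohort(spec, default_atlas, mode="table")


@pytest.fixture()
def fast_config():
    """Reduced three-model bucket for tests that rebuild many times."""
    return BucketConfig(
        models=fast_models(0),
        max_iterations=1,
        use_rfe=False,
        covariate_mode="none",
        floor_eval="test",
    )


def toy_table(n_per_group=10, n_features=4, seed=0, effect=0.0):
    """Small two-group feature table with optional mean shift in feature 0."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.poisson(20, size=(n, n_features)).astype(np.int64)
    X[n_per_group:, 0] += int(round(effect))
    ids = [f"S{i:03d}" for i in range(n)]
    counts = pd.DataFrame(X, index=pd.Index(ids, name="subject_id"),
                          columns=[f"region_{j}" for j in range(n_features)])
    meta = pd.DataFrame(
        {
            "group": ["CFS"] * n_per_group + ["GWI"] * n_per_group,
            "age": rng.normal(47, 8, n),
            "bmi": rng.normal(28, 5, n),
            "sex": rng.choice(["M", "F"], n),
            "day": 1,
        },
        index=counts.index,
    )
    return FeatureTable(counts, meta, list(range(1, n_features + 1)))
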