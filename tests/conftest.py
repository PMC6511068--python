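import numpy as np
import pandas as pd
import pytest

from hpsig import HPSConfig, default_cohort_spec, simulate_cohort
from hpsig.pipeline import tag_simulated_cohorts


@pytest.fixture(scope="session")
def fast_config():
    """Reduced two-stage configuration for quick fits in tests."""
    return HPSConfig(
        stage1_splits=10,
        n_subsamples=50,
        subsample_fraction=0.5,
        stage2_splits=25,
        svm_C_grid=tuple(np.logspace(-2, 1, 5)),
        stage2_C_grid=tuple(np.logspace(-2, 1, 5)),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Quarter-scale simulated cohort with train/validation/test tags."""
    table = simulate_cohort(default_cohort_spec(scale=0.25), seed=1)
    return tag_simulated_cohorts(table, 1)


@pytest.fixture(scope="session")
def train_table(small_cohort):
    return small_cohort[small_cohort["cohort"] == "train"].reset_index(drop=True)


@pytest.fixture(scope="session")
def validation_table(small_cohort):
    return small_cohort[small_cohort["cohort"] == "validation"].reset_index(drop=True)


def make_confounds(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.uniform(60, 90, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "mean_gmv": rng.normal(0.45, 0.03, n),
        "tiv": rng.normal(1450, 100, n),
    })


def toy_feature_table(n_per_class=20, sep=6.0, seed=0, diagnoses=("CN", "AD")):
    """Two-class table over the VCOG columns, classes separated on the
    cognitive block by ``sep`` standard deviations."""
    rng = np.random.default_rng(seed)
    cfg = HPSConfig()
    rows = []
    for j, diag in enumerate(diagnoses):
        X = rng.standard_normal((n_per_class, len(cfg.columns)))
        X[:, 4:9] += j * sep
        for row in X:
            rows.append([diag, *row])
    table = pd.DataFrame(rows, columns=["diagnosis", *cfg.columns])
    table.insert(0, "participant_id", [f"{diagnoses[0]}{diagnoses[1]}{i}"
                                       for i in range(len(table))])
    return table


def orthogonal_templates(v, k=2, seed=0):
    """k mutually orthogonal random template maps of v voxels."""
    rng = np.random.default_rng(seed)
    T = rng.standard_normal((k, v))
    for i in range(1, k):
        for j in range(i):
            T[i] -= (T[i] @ T[j]) / (T[j] @ T[j]) * T[j]
    return T
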