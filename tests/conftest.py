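import numpy as np
import pytest

from fedomics import CohortSpec, FeatureMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A fast 140-sample cohort with reduced feature blocks."""
    return CohortSpec(
        n_cases=40, n_controls=100, n_snp=15, n_expr=20, n_clin=5, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_matrix(small_cohort) -> FeatureMatrix:
    return small_cohort[0]


def make_matrix(labels, values=None, seed=0) -> FeatureMatrix:
    """Hand-built FeatureMatrix for partition/metric plumbing tests."""
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    if values is None:
        values = rng.normal(size=(n, 3))
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    return FeatureMatrix(
        sample_ids=np.array([f"S{i:04d}" for i in range(n)], dtype=object),
        labels=labels,
        values=values,
        feature_names=np.array([f"F{j}" for j in range(p)], dtype=object),
        feature_groups=np.array(["clinical"] * p, dtype=object),
    )
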