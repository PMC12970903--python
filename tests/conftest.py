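import numpy as np
import pytest

from scnkit import CohortConfig, CovarianceSpec, generate_cohort


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal, edge probability p."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.int8)
    return adj + adj.T


def fast_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """16-region, 4-module cohort used throughout the tests."""
    defaults = dict(n_regions=16, covariance=CovarianceSpec(n_modules=4),
                    seed=seed)
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 16-region cohort shared by read-only tests."""
    return generate_cohort(fast_cohort_config(seed=42))
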