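import numpy as np
import pytest

from connpredict.synthetic import CohortConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_correlation(rng, n_regions):
    """A random valid correlation matrix (factor construction)."""
    F = rng.standard_normal((n_regions, n_regions + 5))
    C = np.corrcoef(F)
    np.fill_diagonal(C, 1.0)
    return C


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with strong planted signal (5 regions out of 40)."""
    cfg = CohortConfig(n_subjects=30, n_regions=40,
                       planted_regions=(0, 8, 16, 24, 32),
                       effect_size=0.5, noise_sd=0.05, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose score is independent of every connectivity feature."""
    cfg = CohortConfig(n_subjects=30, n_regions=40, planted_regions=(),
                       effect_size=0.0, noise_sd=0.05, seed=11)
    return simulate_cohort(cfg)


def strengths_of(cohort):
    from connpredict.features import nodal_strength
    return np.vstack([nodal_strength(c).strengths for c in cohort.connectomes])
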