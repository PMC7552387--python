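import numpy as np
import pytest

from equibench.synth_cohort import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast two-group cohort with both kinds of discrepancy present."""
    cfg = SyntheticConfig(
        n1=120, n2=60, n_features=30, n_de=5, beta_counts=(10, 5, 5, 10), seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """The smallest cohort on which the full suite still runs."""
    cfg = SyntheticConfig(
        n1=40, n2=24, n_features=10, n_de=2, beta_counts=(3, 2, 2, 3), seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
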