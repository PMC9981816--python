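import numpy as np
import pytest

from cogem import SyntheticConfig, generate_dataset, run_subject_cv

# Reduced-scale study conditions reused across tests: small enough for fast
# nested CV, large enough that classification is non-trivial.
SMALL_CONFIG = SyntheticConfig(
    n_tasks=10,
    n_features=8,
    n_cognitive=5,
    n_parametric=2,
    n_regions=60,
    n_networks=3,
    n_subjects=2,
    n_four_session_tasks=3,
    seed=11,
)
SMALL_INNER_K = 4


@pytest.fixture(scope="session")
def small_sim():
    """(feature matrix, ground truth, dataset) at reduced scale."""
    return generate_dataset(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_splits(small_sim):
    """Leave-two-out results for the first synthetic subject."""
    fm, _, data = small_sim
    return run_subject_cv(
        data.subjects[0], fm, inner_k=SMALL_INNER_K,
        rng=np.random.default_rng(0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
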