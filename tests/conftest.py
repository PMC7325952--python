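import numpy as np
import pytest

from slongdina import GeneratingConfig, SLongDINA, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complete dataset shared by quick estimator/evaluation tests."""
    return simulate_dataset(GeneratingConfig(n_persons=60, items_per_time=15, seed=7))


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset):
    """A short (non-converged is fine) fit for plumbing-level assertions."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = SLongDINA(n_iter=400, burn_in=200, random_state=99).fit(
            tiny_dataset.responses, tiny_dataset.q_matrix
        )
    return est
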