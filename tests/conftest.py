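import numpy as np
import pytest

from latentcause import InternalModel, TaskParams, sample_trial


@pytest.fixture
def model():
    return InternalModel()


@pytest.fixture
def task():
    return TaskParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_trials(n, N_range=(2, 8), seed=0, params=None):
    """Draw trials from the generative model with N uniform over a range."""
    params = params or TaskParams()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        N = int(rng.integers(N_range[0], N_range[1] + 1))
        out.append(sample_trial(params, N, rng))
    return out
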