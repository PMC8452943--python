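import numpy as np
import pytest

import cdmkit as ck


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def space2():
    return ck.enumerate_patterns(2)


@pytest.fixture
def q_small():
    """Three-item, two-attribute Q-matrix: A1, A2, and A1+A2."""
    return ck.QMatrix(entries=np.array([[1, 0], [0, 1], [1, 1]]))


@pytest.fixture
def small_sim(rng):
    """A quick saturated-truth dataset: K=3, J=12, N=800."""
    q = ck.default_qmatrix(J=12, K=3)
    profiles = ck.generate_profiles(800, 3, rng=rng)
    truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
    X = ck.simulate_responses(truth, profiles, rng)
    return q, truth, profiles, X
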