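import numpy as np
import pytest

from eegfc.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small, fast cohort: 3 subjects, 16-s recordings, 4 epochs."""
    return SynthConfig(n_subjects=3, duration_s=16.0, n_epochs=4, seed=99)


def random_weighted_graph(rng, n=None, p_edge=0.6, w_lo=0.05, w_hi=1.0):
    """Random symmetric weight matrix with zero diagonal (test helper)."""
    if n is None:
        n = int(rng.integers(2, 7))
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < p_edge
    w[iu] = rng.uniform(w_lo, w_hi, len(iu[0])) * mask
    return w + w.T
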