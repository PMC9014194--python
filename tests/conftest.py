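import numpy as np
import pytest

from fstatpca import AlleleFreqMatrix


def make_freqs(rng, n=6, s=100, lo=0.0, hi=1.0, labels=None):
    """Random frequency matrix with labels P0..P{n-1} (or given labels)."""
    if labels is None:
        labels = tuple(f"P{i}" for i in range(n))
    return AlleleFreqMatrix(rng.uniform(lo, hi, (n, s)), labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_freqs(rng):
    return make_freqs(rng)


@pytest.fixture
def collinear_triple():
    """Three collinear populations (0,0), (0.5,0.5), (1,1) at S=2.

    Pairwise F2 off-diagonals are 0.25, 0.25 and 1.0; the configuration
    is rank one, with a single positive eigenvalue 0.5 and PC1
    coordinates (-0.5, 0, 0.5) up to the global sign convention.
    """
    return AlleleFreqMatrix(
        np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 1.0]]),
        ("end1", "mid", "end2"),
    )
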