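import numpy as np
import pytest

from orthoflow import PISUM_CTIRAD, BMSimConfig, simulate_tree_and_tips


@pytest.fixture
def pisum():
    return PISUM_CTIRAD


@pytest.fixture
def small_tree():
    """A 7-tip unit-height pure-birth tree with BM tip values."""
    phy, tips = simulate_tree_and_tips(
        BMSimConfig(n_tips=7, scale_height=1.0, seed=42))
    return phy, tips


def exact_gaussian_histogram(mean, sd, n_bins=1024, n=5000):
    """Deterministic discretized Gaussian counts (not a random draw)."""
    centers = np.arange(n_bins, dtype=float)
    dens = np.exp(-0.5 * ((centers - mean) / sd) ** 2)
    return centers, n * dens / dens.sum()
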