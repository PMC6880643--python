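import numpy as np
import pytest

from dgselect import data_io, weighting


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def separable_dataset():
    """Tiny two-class dataset with one cleanly separating attribute."""
    rng = np.random.default_rng(7)
    n = 40
    X = rng.normal(size=(n, 6))
    labels = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    X[labels == "pos", 0] += 8.0  # margin far beyond the noise
    return X, labels


@pytest.fixture
def small_planted_dataset():
    """Planted-signal dataset small enough for fast evolution runs."""
    spec = data_io.SyntheticSpec(
        n_samples=40, n_attributes=120, n_informative=3, effect_size=2.5, seed=11
    )
    return data_io.synthesize(spec)


@pytest.fixture
def weight_table():
    """Five attributes with strictly decreasing weights a0 > a1 > ... > a4."""
    return weighting.WeightTable.from_ranks(
        ["a0", "a1", "a2", "a3", "a4"], [5.0, 4.0, 3.0, 2.0, 1.0]
    )
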