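import numpy as np
import pytest

from ironnorm import ChipLayout, ExpressionMatrix, PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """3 features × 2 samples, strictly positive."""
    return ExpressionMatrix(
        ["p1", "p2", "p3"],
        ["s1", "s2"],
        np.array([[10.0, 20.0], [100.0, 150.0], [1000.0, 900.0]]),
    )


@pytest.fixture
def simple_layout():
    return ChipLayout(
        probe_to_probeset={"p1": "A", "p2": "A", "p3": "B", "p4": "B"},
        masked={"p2"},
        qc_probes={"p4"},
    )


@pytest.fixture
def loose_config():
    """Config usable on small vectors (default min_training_size is 100)."""
    return PipelineConfig(min_training_size=10)


def random_chip(rng, n, log2_mean=11.0, log2_sd=2.5, expo_mean=200.0, bg_mu=100.0):
    """Strictly positive intensities with realistic array structure."""
    signal = np.power(2.0, rng.normal(log2_mean, log2_sd, n)) + rng.exponential(expo_mean, n)
    return signal + bg_mu
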