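import numpy as np
import pytest

from clonaltraj.core import BarcodeTimeSeries, FrequencyMatrix, to_frequencies


@pytest.fixture
def small_series() -> BarcodeTimeSeries:
    """3 barcodes x 4 timepoints with distinct, hand-checkable counts."""
    counts = np.array(
        [
            [10, 20, 30, 40],
            [90, 60, 50, 40],
            [0, 20, 20, 20],
        ]
    )
    return BarcodeTimeSeries(["A", "B", "C"], np.array([0.0, 1.0, 2.0, 3.0]), counts)


@pytest.fixture
def small_freqs(small_series) -> FrequencyMatrix:
    return to_frequencies(small_series)


def random_series(rng: np.random.Generator, n_barcodes=6, n_timepoints=5,
                  max_count=500) -> BarcodeTimeSeries:
    counts = rng.integers(0, max_count, size=(n_barcodes, n_timepoints))
    # keep every column total positive
    counts[0] += 1
    ids = [f"bc{i:03d}" for i in range(n_barcodes)]
    return BarcodeTimeSeries(ids, np.arange(n_timepoints, dtype=float), counts)


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(n))
    return x / x.sum()
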