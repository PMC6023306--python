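from itertools import combinations

import numpy as np
import pytest

from voxcorr import TimeSeriesMatrix, pcc_direct


def condensed_oracle(values: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs Pearson correlations via the definitional
    centered formula, in condensed row-major order. Independent of the
    blocked gemm path under test."""
    n = values.shape[0]
    return np.array(
        [pcc_direct(values[i], values[j]) for i, j in combinations(range(n), 2)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def anticorrelated_trio() -> TimeSeriesMatrix:
    """Three voxels with exact ±1 correlations: rows 1 and 3 identical,
    row 2 their reflection."""
    return TimeSeriesMatrix([[1, 2, 3], [3, 2, 1], [1, 2, 3]], voxel_order_tag="fixture")
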