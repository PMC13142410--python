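import numpy as np
import pandas as pd
import pytest

from cocotag.barcodes import BarcodeScheme
from cocotag.sim import SimConfig


@pytest.fixture(scope="session")
def scheme() -> BarcodeScheme:
    return BarcodeScheme.synthetic(seed=7)


@pytest.fixture()
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_cells=30, mean_reads_per_cell=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_overlap_counts(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """O(n*m) interval-overlap oracle (half-open, >=1 bp)."""
    out = np.zeros(len(query), dtype=int)
    for qi, q in enumerate(query.itertuples(index=False)):
        for t in targets.itertuples(index=False):
            if t.chrom == q.chrom and t.start < q.end and q.start < t.end:
                out[qi] += 1
    return out
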