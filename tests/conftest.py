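import numpy as np
import pandas as pd
import pytest

from combind.core import PeakSet
from combind.synthetic_data import SimulationConfig, simulate

CHROM_SIZES = {"chr1": 1_000_000, "chr2": 800_000}


def make_peakset(intervals, experiment="expA", factor="FA", genome="g",
                 chrom_sizes=None, scores=None):
    """Build a PeakSet from (chrom, start, end) triples."""
    chrom_sizes = chrom_sizes or CHROM_SIZES
    df = pd.DataFrame(
        {
            "chrom": [iv[0] for iv in intervals],
            "start": np.array([iv[1] for iv in intervals], dtype=np.int64),
            "end": np.array([iv[2] for iv in intervals], dtype=np.int64),
            "score": np.asarray(scores, dtype=float) if scores is not None
            else np.zeros(len(intervals)),
            "summit": [None] * len(intervals),
        }
    )
    return PeakSet(df, experiment, factor, genome, chrom_sizes)


def random_intervals(rng, n, chrom_sizes=None, max_width=500):
    chrom_sizes = chrom_sizes or CHROM_SIZES
    chroms = list(chrom_sizes)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        w = int(rng.integers(1, max_width))
        s = int(rng.integers(0, chrom_sizes[c] - w))
        out.append((c, s, s + w))
    return out


@pytest.fixture
def chrom_sizes():
    return dict(CHROM_SIZES)


@pytest.fixture(scope="session")
def default_bundle():
    """One deterministic synthetic study bundle shared across tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(SimulationConfig(seed=5, n_hotspots=150, genome_size=4_000_000))
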