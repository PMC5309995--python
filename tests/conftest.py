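import numpy as np
import pytest

from nucleotool import occupancy as occ
from nucleotool import simulate as sim
from nucleotool.fragments import FragmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_fragments(rng, chrom="chr1", span=10_000, n=200, max_len=300):
    """Random small fragment set for oracle comparisons."""
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return FragmentSet(chrom, np.sort(starts), np.sort(starts) + lengths)


def brute_force_coverage(frags: FragmentSet, length: int) -> np.ndarray:
    """O(n * L) per-base coverage oracle."""
    cov = np.zeros(length)
    for f in frags:
        cov[f.start : min(f.end, length)] += 1
    return cov


def tracks_from_fragsets(fragsets, window=100):
    return [occ.compute_windowed_occupancy(fs, window) for fs in fragsets]


@pytest.fixture(scope="session")
def array_fragments_190():
    """Medium regular-array simulation shared across tests."""
    model = sim.ArrayModel(
        chrom_length=2_000_000, nrl_true=190, jitter_sd=20.0, depth=5, frag_len_sd=8.0, seed=42
    )
    return sim.simulate_array_reads(model)
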