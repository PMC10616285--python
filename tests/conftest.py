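import numpy as np
import pytest

from airway_epi.intervals import ChromSizes, GenomicInterval, TSSRecord
from airway_epi.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 80_000, "chrY": 20_000, "chrM": 16_000})


@pytest.fixture
def small_sim_config():
    """A reduced design that still mirrors the 5-vs-4 replicate structure."""
    return SimulationConfig(
        seed=7,
        chrom_sizes={"chr1": 200_000, "chr2": 150_000, "chrY": 30_000, "chrM": 16_000},
        n_genes=20,
        n_true_peaks=60,
        base_depth=8_000,
        noise_peaks_per_sample=5,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=300):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
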