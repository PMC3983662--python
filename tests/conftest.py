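import numpy as np
import pytest

from peakscape.core import CoverageTrack, GenomeModel, Interval
from peakscape.simulate import SimulationConfig, simulate


@pytest.fixture
def genome():
    return GenomeModel(
        {"chrI": 10_000, "chrII": 8_000, "chrX": 9_000, "chrM": 500},
        x_chrom="chrX",
        excluded_chroms={"chrM"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, genome, n, min_len=50, max_len=500, chroms=None):
    """Uniformly placed intervals for oracle comparisons."""
    chroms = chroms or genome.included_chroms
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, genome.length(chrom) - 1)
        start = int(rng.integers(0, genome.length(chrom) - length))
        out.append(Interval(chrom, start, start + length))
    return out


def perbase_cover(intervals, genome):
    """Brute-force per-base boolean coverage map."""
    cover = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chrom_names}
    for iv in intervals:
        cover[iv.chrom][iv.start : iv.end] = True
    return cover


def brute_hit_flags(a, b, min_overlap=1):
    """O(n*m) per-pair overlap oracle, independent of the sweep implementation."""
    flags = np.zeros(len(a), dtype=bool)
    for i, x in enumerate(a):
        for y in b:
            if x.chrom == y.chrom:
                if min(x.end, y.end) - max(x.start, y.start) >= min_overlap:
                    flags[i] = True
                    break
    return flags


@pytest.fixture
def random_track(genome, rng):
    return CoverageTrack(
        {c: rng.poisson(5.0, genome.length(c)).astype(float) for c in genome.chrom_names},
        genome,
    )


SMALL_SIM = dict(
    n_chroms=3,
    chrom_length=40_000,
    n_genes_per_chrom=15,
    n_trnas_per_chrom=3,
    n_ncrnas_per_chrom=4,
    n_enhancers_per_complex=12,
)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(SimulationConfig(**SMALL_SIM), seed=7)
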