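import numpy as np
import pytest

from relochip.genome_core import GeneModel, GenomicInterval
from relochip.synthetic_data import SimConfig, Simulation


@pytest.fixture(scope="session")
def default_sim() -> Simulation:
    """The default synthetic study (2 x 1 Mb, 20 planted peaks per
    condition at 20x enrichment, seed 7) shared across test modules."""
    return Simulation(SimConfig())


@pytest.fixture(scope="session")
def default_reads(default_sim):
    """Baseline ChIP + control channels of the default study."""
    return (
        default_sim.simulate_reads("baseline", "chip"),
        default_sim.simulate_reads("baseline", "control"),
    )


@pytest.fixture()
def toy_genes() -> list[GeneModel]:
    """Hand-laid genes on one 100 kb chromosome for rule-level checks."""
    return [
        GeneModel(
            "geneA", "chr1", "+", 10_000, 20_000,
            exons=(
                GenomicInterval("chr1", 10_000, 11_000, "+"),
                GenomicInterval("chr1", 15_000, 16_000, "+"),
                GenomicInterval("chr1", 19_000, 20_000, "+"),
            ),
        ),
        GeneModel(
            "geneB", "chr1", "-", 40_000, 50_000,
            exons=(
                GenomicInterval("chr1", 40_000, 41_000, "-"),
                GenomicInterval("chr1", 49_000, 50_000, "-"),
            ),
        ),
    ]


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_pos: int = 100_000, max_len: int = 2_000) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
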