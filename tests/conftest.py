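import numpy as np
import pytest

from chromode import GeneModel, GenomeLayout, GenomicInterval, SimConfig, simulate
from chromode.expression import ExpressionTable


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic run shared by the slower integration tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A light simulation for quick structural checks."""
    cfg = SimConfig(seed=3, n_chroms=1, chrom_length=2_000_000, n_genes=40,
                    tags_per_library=50_000)
    return simulate(cfg)


@pytest.fixture
def toy_genes():
    return [
        GeneModel("gA", "chr1", "+", 10_000, 30_000),
        GeneModel("gB", "chr1", "-", 80_000, 60_000),
        GeneModel("gC", "chr2", "+", 5_000, 9_000),
    ]


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=2_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            GenomicInterval(str(rng.choice(chroms)), start,
                            start + int(rng.integers(1, max_len)))
        )
    return out


def expression_from_sim(sim) -> ExpressionTable:
    return ExpressionTable(sim.fpkm, sim.design)
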