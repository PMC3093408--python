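import numpy as np
import pytest

from ervscape.model import LTRFeature, ProviralChain, Putein
from ervscape.simulate import SimulationConfig, simulate_genome


def make_chain(
    id=1,
    chromosome="chr1",
    start=0,
    end=10_000,
    strand="+",
    score=500.0,
    genus="unclassified",
    putein_genes=(),
    ltr5=None,
    ltr3=None,
    pbs=None,
):
    """Compact ProviralChain builder; putein_genes is a sequence of gene
    names or (gene, sequence) pairs."""
    puteins = []
    for item in putein_genes:
        if isinstance(item, tuple):
            gene, seq = item
        else:
            gene, seq = item, "M" * 40
        puteins.append(Putein(gene=gene, sequence=seq))
    return ProviralChain(
        id=id,
        chromosome=chromosome,
        start=start,
        end=end,
        strand=strand,
        score=score,
        genus=genus,
        puteins=puteins,
        ltr5=ltr5,
        ltr3=ltr3,
        pbs=pbs,
    )


def make_ltr(start, end, sequence=None):
    return LTRFeature(start=start, end=end, sequence=sequence)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=7, n_chromosomes=4, n_ervs=30, n_genes=60, n_gaps=20
    )
    return simulate_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
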