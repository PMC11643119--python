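"""Shared fixtures: a tiny hand-built annotation and a small simulation."""

import pytest

from iclipkit.core import GeneModel, GenomeSequence, Interval
from iclipkit.simulate import SimConfig, make_genome


@pytest.fixture
def plus_gene() -> GeneModel:
    """Protein-coding gene on '+': 5'UTR [100,200), CDS [200,400) and
    [500,700), intron [400,500), 3'UTR [700,800)."""
    c = "chr1"
    return GeneModel(
        gene_id="GP",
        chrom=c,
        strand="+",
        biotype="protein_coding",
        tss=100,
        representative_tx_id="GP.1",
        features=[
            ("five_prime_UTR", Interval(c, 100, 200)),
            ("CDS", Interval(c, 200, 400)),
            ("intron", Interval(c, 400, 500)),
            ("CDS", Interval(c, 500, 700)),
            ("three_prime_UTR", Interval(c, 700, 800)),
            ("exon", Interval(c, 100, 400)),
            ("exon", Interval(c, 500, 800)),
        ],
        donors=[400],
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    """Mirror-image gene on '-': exons [1100,1400) and [1500,1800) with
    the 5'UTR at the high-coordinate end."""
    c = "chr1"
    mk = lambda s, e: Interval(c, s, e, "-")
    return GeneModel(
        gene_id="GM",
        chrom=c,
        strand="-",
        biotype="protein_coding",
        tss=1799,
        representative_tx_id="GM.1",
        features=[
            ("five_prime_UTR", mk(1700, 1800)),
            ("CDS", mk(1500, 1700)),
            ("intron", mk(1400, 1500)),
            ("CDS", mk(1200, 1400)),
            ("three_prime_UTR", mk(1100, 1200)),
            ("exon", mk(1500, 1800)),
            ("exon", mk(1100, 1400)),
        ],
        donors=[1499],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A deterministic 30-gene simulated genome shared across tests."""
    cfg = SimConfig(n_genes=30, n_signal_peaks=300, seed=11)
    return cfg, make_genome(cfg)


@pytest.fixture
def flat_genome() -> GenomeSequence:
    return GenomeSequence({"chr1": "ACGT" * 600})
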