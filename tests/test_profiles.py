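"""Positional metaprofiles: offsets, PFMs, motif distances, symmetry."""

import random

import pytest

from iclipkit.core import GeneModel, GenomeSequence, Interval, reverse_complement
from iclipkit.profiles import (
    distances_to_donors,
    distances_to_tss,
    find_motif_occurrences,
    scan_motif_and_distances,
    window_matrix,
)
from iclipkit.sites import BindingSite


def _site(pos, strand="+", chrom="chr1"):
    return BindingSite(chrom, strand, pos - 4, pos + 5, pos, 1.0)


def _gene(chrom, strand, tss, features, donors, gene_id="g"):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, biotype="protein_coding",
        tss=tss, representative_tx_id=gene_id + ".1", features=features,
        donors=donors,
    )


def _simple_plus_gene(start=1000, exon=200, intron=100, n_exons=2, chrom="chr1"):
    features = []
    pos = start
    donors = []
    for i in range(n_exons):
        features.append(("exon", Interval(chrom, pos, pos + exon)))
        features.append(("CDS", Interval(chrom, pos, pos + exon)))
        pos += exon
        if i < n_exons - 1:
            features.append(("intron", Interval(chrom, pos, pos + intron)))
            donors.append(pos)
            pos += intron
    return _gene(chrom, "+", start, features, donors)


class TestTssDistances:
    def test_plus_strand_offset(self):
        g = _simple_plus_gene(start=1000)
        prof = distances_to_tss([_site(1050)], [g])
        assert dict(prof.offsets) == {50: 1}

    def test_minus_strand_offset(self):
        c = "chr1"
        g = _gene(
            c, "-", 2000,
            [("exon", Interval(c, 1800, 2001, "-")),
             ("CDS", Interval(c, 1800, 2001, "-"))],
            [],
        )
        prof = distances_to_tss([_site(1950, "-")], [g])
        assert dict(prof.offsets) == {50: 1}

    def test_beyond_window_ignored(self):
        g = _simple_plus_gene(start=1000, exon=400)
        prof = distances_to_tss([_site(1300)], [g], max_downstream=250)
        assert prof.total() == 0

    def test_unassigned_sites_ignored(self):
        g = _simple_plus_gene(start=1000)
        assert distances_to_tss([_site(5000)], [g]).total() == 0


class TestDonorDistances:
    def test_exonic_offset_is_negative(self):
        # exon [1000,1200), donor at 1200, peak 1173 -> -27
        g = _simple_plus_gene(start=1000, exon=200)
        prof = distances_to_donors([_site(1173)], [g])
        assert dict(prof.offsets) == {-27: 1}

    def test_short_upstream_exon_excluded(self):
        g = _simple_plus_gene(start=1000, exon=40)
        prof = distances_to_donors([_site(1035)], [g], min_exon_len=50)
        assert prof.total() == 0

    def test_matches_pairwise_oracle(self):
        rng = random.Random(6)
        genes = [
            _simple_plus_gene(start=1000 + 2000 * i,
                              exon=rng.choice([40, 80, 200]),
                              n_exons=rng.randrange(2, 5))
            for i in range(5)
        ]
        sites = [
            _site(rng.randrange(1000, 11000)) for _ in range(200)
        ]
        window, min_len = (-50, 10), 50
        prof = distances_to_donors(sites, genes, min_exon_len=min_len,
                                   window=window)
        oracle: dict[int, int] = {}
        for g in genes:
            span = g.span()
            g_sites = [s for s in sites
                       if s.start < span.end and span.start < s.end]
            for donor, elen in zip(g.donors, g.donor_upstream_exon_lengths()):
                if elen < min_len:
                    continue
                for s in g_sites:
                    off = s.peak - donor
                    if window[0] <= off <= window[1]:
                        oracle[off] = oracle.get(off, 0) + 1
        assert dict(prof.offsets) == oracle
        assert prof.total() == sum(oracle.values())


class TestWindowMatrix:
    def test_all_c_genome(self):
        genome = GenomeSequence({"chr1": "C" * 300})
        pfm = window_matrix([_site(150)], genome, width=21)
        assert pfm.n_sequences == 1
        assert (pfm.counts[1] == 1).all()  # row C
        assert pfm.counts.sum() == 21

    def test_even_width_rejected(self):
        genome = GenomeSequence({"chr1": "C" * 300})
        with pytest.raises(ValueError):
            window_matrix([_site(150)], genome, width=20)

    def test_edge_peaks_skipped(self):
        genome = GenomeSequence({"chr1": "C" * 100})
        pfm = window_matrix([_site(5), _site(50)], genome, width=21)
        assert pfm.n_sequences == 1

    def test_matches_tally_oracle(self):
        rng = random.Random(2)
        genome = GenomeSequence(
            {"chr1": "".join(rng.choice("ACGTN") for _ in range(500))}
        )
        sites = [_site(rng.randrange(15, 485), rng.choice("+-"))
                 for _ in range(10)]
        pfm = window_matrix(sites, genome, width=11)
        seqs = [
            genome.fetch(Interval("chr1", s.peak - 5, s.peak + 6, s.strand))
            for s in sites
        ]
        for pos in range(11):
            col = pfm.column(pos)
            for bi, base in enumerate("ACGT"):
                assert col[base] == sum(1 for q in seqs if q[pos] == base)
            # column sums + skipped N == number of stacked sequences
            assert sum(col.values()) + pfm.n_skipped[pos] == pfm.n_sequences


class TestMotifScan:
    def test_exact_match_position(self):
        genome = GenomeSequence({"chr1": "GGCAGAGG"})
        occ = find_motif_occurrences(genome, "CAGA")
        assert list(occ[("chr1", "+")]) == [2]

    def test_minus_strand_first_base(self):
        # '-' strand CAGA appears where '+' carries TCTG; first base (C)
        # is the rightmost genomic coordinate of the match
        genome = GenomeSequence({"chr1": "AATCTGAA"})
        occ = find_motif_occurrences(genome, "CAGA")
        assert list(occ[("chr1", "-")]) == [5]
        assert genome.fetch(Interval("chr1", 2, 6, "-")) == "CAGA"

    def test_peak_on_first_base_offset_zero(self):
        genome = GenomeSequence({"chr1": "G" * 50 + "CAGA" + "G" * 50})
        prof = scan_motif_and_distances([_site(50)], genome)
        assert dict(prof.offsets) == {0: 1}

    def test_tie_counts_toward_upstream_occurrence(self):
        # occurrences at 40 and 60, peak at 50: distance 10 both ways;
        # upstream (5' on '+') occurrence wins -> positive offset
        genome = GenomeSequence(
            {"chr1": "G" * 40 + "CAGA" + "G" * 16 + "CAGA" + "G" * 40}
        )
        prof = scan_motif_and_distances([_site(50)], genome)
        assert dict(prof.offsets) == {10: 1}

    def test_invalid_motif_rejected(self):
        genome = GenomeSequence({"chr1": "ACGT" * 10})
        with pytest.raises(ValueError):
            scan_motif_and_distances([_site(20)], genome, motif="CAGX")

    def test_matches_nearest_occurrence_oracle(self):
        rng = random.Random(12)
        genome = GenomeSequence(
            {"chr1": "".join(rng.choice("ACGT") for _ in range(2000))}
        )
        sites = [_site(rng.randrange(25, 1975), rng.choice("+-"))
                 for _ in range(100)]
        window = (-20, 20)
        prof = scan_motif_and_distances(sites, genome, "CAGA", window)
        occ = find_motif_occurrences(genome, "CAGA")
        oracle: dict[int, int] = {}
        for s in sites:
            positions = occ[("chr1", s.strand)]
            if len(positions) == 0:
                continue
            sign = 1 if s.strand == "+" else -1
            offs = [(abs(s.peak - p), -sign * (s.peak - p)) for p in positions]
            d, negoff = min(offs)
            off = -negoff
            if window[0] <= off <= window[1]:
                oracle[off] = oracle.get(off, 0) + 1
        assert dict(prof.offsets) == oracle


def _mirror_models(models, sizes):
    out = []
    for g in models:
        L = sizes[g.chrom]
        flip = "-" if g.strand == "+" else "+"
        feats = [
            (t, Interval(g.chrom, L - iv.end, L - iv.start, flip))
            for t, iv in g.features
        ]
        out.append(
            GeneModel(
                gene_id=g.gene_id, chrom=g.chrom, strand=flip,
                biotype=g.biotype, tss=L - 1 - g.tss,
                representative_tx_id=g.representative_tx_id,
                features=feats, donors=[L - 1 - d for d in g.donors],
            )
        )
    return out


def _mirror_sites(sites, sizes):
    out = []
    for s in sites:
        L = sizes[s.chrom]
        flip = "-" if s.strand == "+" else "+"
        out.append(
            BindingSite(s.chrom, flip, L - s.end, L - s.start,
                        L - 1 - s.peak, s.score, s.clipped)
        )
    return out


class TestStrandSymmetry:
    """Reverse-complementing the genome and flipping every strand leaves
    all three profiles unchanged."""

    def _setup(self):
        rng = random.Random(31)
        seq = "".join(rng.choice("ACGT") for _ in range(4000))
        genome = GenomeSequence({"chr1": seq})
        mirrored = GenomeSequence({"chr1": reverse_complement(seq)})
        genes = [
            _simple_plus_gene(start=200 + 1200 * i, exon=150, n_exons=3)
            for i in range(3)
        ]
        sites = [_site(random.Random(41 + i).randrange(200, 3800),
                       "+" if i % 2 else "-") for i in range(60)]
        sizes = genome.chrom_sizes()
        return genome, mirrored, genes, sites, sizes

    def test_all_profiles_invariant(self):
        genome, mirrored, genes, sites, sizes = self._setup()
        m_genes = _mirror_models(genes, sizes)
        m_sites = _mirror_sites(sites, sizes)

        tss_a = distances_to_tss(sites, genes)
        tss_b = distances_to_tss(m_sites, m_genes)
        assert dict(tss_a.offsets) == dict(tss_b.offsets)

        don_a = distances_to_donors(sites, genes)
        don_b = distances_to_donors(m_sites, m_genes)
        assert dict(don_a.offsets) == dict(don_b.offsets)

        mot_a = scan_motif_and_distances(sites, genome)
        mot_b = scan_motif_and_distances(m_sites, mirrored)
        assert dict(mot_a.offsets) == dict(mot_b.offsets)

        pfm_a = window_matrix(sites, genome)
        pfm_b = window_matrix(m_sites, mirrored)
        assert (pfm_a.counts == pfm_b.counts).all()
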