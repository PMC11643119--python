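"""Binding-site pipeline: literal-rule oracles and boundary behaviour."""

import random

import pytest
from hypothesis import given, settings, strategies as hst

from iclipkit.sites import (
    BindingSite,
    CrosslinkPeak,
    ReadRecord,
    assign_features,
    collapse_adjacent_peaks,
    dedup_reads,
    define_binding_sites,
    feature_category_percentages,
    subtract_control,
)


def _random_reads(rng, n):
    return [
        ReadRecord(
            chrom=rng.choice(["chr1", "chr2"]),
            strand=rng.choice("+-"),
            start=rng.randrange(0, 50),
            barcode=rng.choice(["AACG", "TTTT", "GGGG"]),
        )
        for _ in range(n)
    ]


class TestDedupReads:
    def test_identical_key_collapses(self):
        r = ReadRecord("chr1", "+", 100, "AACG")
        assert dedup_reads([r, r]) == [r]

    def test_distinct_barcodes_kept(self):
        a = ReadRecord("chr1", "+", 100, "AACG")
        b = ReadRecord("chr1", "+", 100, "TTTT")
        assert dedup_reads([a, b]) == [a, b]

    def test_matches_set_oracle_and_idempotent(self):
        rng = random.Random(5)
        reads = _random_reads(rng, 1000)
        out = dedup_reads(reads)
        oracle = len({(r.chrom, r.strand, r.start, r.barcode) for r in reads})
        assert len(out) == oracle
        assert dedup_reads(out) == out


def _collapse_oracle(peaks):
    """O(n^2) literal restatement: maximal runs of consecutive positions
    per chrom/strand, best score wins, tie -> 5'-most."""
    out = []
    for key in sorted({(p.chrom, p.strand) for p in peaks}):
        group = sorted([p for p in peaks if (p.chrom, p.strand) == key],
                       key=lambda p: p.pos)
        runs, current = [], []
        for p in group:
            if current and p.pos == current[-1].pos + 1:
                current.append(p)
            else:
                if current:
                    runs.append(current)
                current = [p]
        if current:
            runs.append(current)
        for run in runs:
            best = max(p.score for p in run)
            tied = [p for p in run if p.score == best]
            out.append(
                min(tied, key=lambda p: p.pos)
                if key[1] == "+"
                else max(tied, key=lambda p: p.pos)
            )
    return out


class TestCollapse:
    def test_adjacent_run_keeps_best(self):
        peaks = [
            CrosslinkPeak("chr1", "+", 100, 2.0),
            CrosslinkPeak("chr1", "+", 101, 5.0),
            CrosslinkPeak("chr1", "+", 102, 1.0),
        ]
        assert collapse_adjacent_peaks(peaks) == [CrosslinkPeak("chr1", "+", 101, 5.0)]

    def test_gap_of_two_passes_through(self):
        peaks = [
            CrosslinkPeak("chr1", "+", 100, 2.0),
            CrosslinkPeak("chr1", "+", 102, 1.0),
        ]
        assert collapse_adjacent_peaks(peaks) == peaks

    @pytest.mark.parametrize("strand,expect", [("+", 100), ("-", 101)])
    def test_score_tie_keeps_five_prime_most(self, strand, expect):
        peaks = [
            CrosslinkPeak("chr1", strand, 100, 3.0),
            CrosslinkPeak("chr1", strand, 101, 3.0),
        ]
        (kept,) = collapse_adjacent_peaks(peaks)
        assert kept.pos == expect

    def test_duplicate_position_rejected(self):
        peaks = [CrosslinkPeak("chr1", "+", 5, 1.0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            collapse_adjacent_peaks(peaks)

    def test_matches_run_decomposition_oracle(self):
        rng = random.Random(7)
        positions = rng.sample(range(0, 400), 200)
        peaks = [
            CrosslinkPeak(
                chrom=rng.choice(["chr1", "chr2"]),
                strand=rng.choice("+-"),
                pos=pos,
                score=round(rng.uniform(0, 5), 2),
            )
            for pos in positions
        ]
        got = collapse_adjacent_peaks(peaks)
        assert sorted(got, key=lambda p: (p.chrom, p.strand, p.pos)) == sorted(
            _collapse_oracle(peaks), key=lambda p: (p.chrom, p.strand, p.pos)
        )


class TestDefineSites:
    SIZES = {"chr1": 1000}

    def test_nine_nt_site_centred_on_peak(self):
        (site,) = define_binding_sites(
            [CrosslinkPeak("chr1", "+", 100, 2.0)], self.SIZES, ext=4
        )
        assert (site.start, site.end, site.peak, len(site)) == (96, 105, 100, 9)
        assert not site.clipped

    def test_edge_clipping_flags_site(self):
        (site,) = define_binding_sites(
            [CrosslinkPeak("chr1", "+", 1, 2.0)], self.SIZES, ext=4
        )
        assert (site.start, site.end, site.clipped) == (0, 6, True)

    def test_ext_zero_is_identity(self):
        peaks = [CrosslinkPeak("chr1", "-", 55, 1.0)]
        (site,) = define_binding_sites(peaks, self.SIZES, ext=0)
        assert (site.start, site.end) == (55, 56)

    def test_peak_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            define_binding_sites(
                [CrosslinkPeak("chr1", "+", 1000, 1.0)], self.SIZES
            )

    def test_nonclipped_width_invariant(self):
        rng = random.Random(3)
        peaks = [
            CrosslinkPeak("chr1", rng.choice("+-"), rng.randrange(4, 996), 1.0)
            for _ in range(100)
        ]
        for s in define_binding_sites(peaks, self.SIZES, ext=4):
            assert len(s) == 9 and s.peak == s.start + 4


def _mk_site(pos, strand="+", chrom="chr1"):
    return BindingSite(chrom, strand, pos - 4, pos + 5, pos, 1.0)


class TestSubtractControl:
    def test_distance_nine_removed_ten_kept(self):
        signal = [_mk_site(100)]
        kept, removed = subtract_control(signal, [_mk_site(109)], window=9)
        assert (kept, removed) == ([], 1)
        kept, removed = subtract_control(signal, [_mk_site(110)], window=9)
        assert (kept, removed) == (signal, 0)

    def test_strand_and_chrom_must_match(self):
        signal = [_mk_site(100, "+")]
        kept, _ = subtract_control(signal, [_mk_site(100, "-")], window=9)
        assert kept == signal
        kept, _ = subtract_control(signal, [_mk_site(100, chrom="chr2")], window=9)
        assert kept == signal

    def test_counts_conserved_and_order_preserved(self):
        rng = random.Random(9)
        signal = [_mk_site(rng.randrange(10, 5000)) for _ in range(300)]
        control = [_mk_site(rng.randrange(10, 5000)) for _ in range(40)]
        kept, removed = subtract_control(signal, control)
        assert len(kept) + removed == len(signal)
        positions = [s.peak for s in signal if s in kept]
        assert [s.peak for s in kept] == positions


class TestPipelineOracle:
    """collapse -> extend -> subtract equals a brute-force restatement."""

    def _oracle(self, sig, ctrl, sizes, ext=4, window=9):
        sig_sites = []
        for p in _collapse_oracle(sig):
            start = max(0, p.pos - ext)
            end = min(sizes[p.chrom], p.pos + ext + 1)
            sig_sites.append((p.chrom, p.strand, start, end, p.pos))
        ctrl_peaks = [(p.chrom, p.strand, p.pos) for p in _collapse_oracle(ctrl)]
        kept = [
            s
            for s in sig_sites
            if not any(
                c[0] == s[0] and c[1] == s[1] and abs(c[2] - s[4]) <= window
                for c in ctrl_peaks
            )
        ]
        return kept

    def test_random_instances(self):
        rng = random.Random(21)
        sizes = {"chr1": 2000, "chr2": 1500}
        for trial in range(20):
            def peaks(n):
                chosen = set()
                out = []
                while len(out) < n:
                    key = (
                        rng.choice(["chr1", "chr2"]),
                        rng.choice("+-"),
                        rng.randrange(0, 1500),
                    )
                    if key in chosen:
                        continue
                    chosen.add(key)
                    out.append(CrosslinkPeak(*key, round(rng.uniform(0, 9), 1)))
                return out

            sig, ctrl = peaks(rng.randrange(5, 120)), peaks(rng.randrange(0, 30))
            collapsed = collapse_adjacent_peaks(sig)
            sites = define_binding_sites(collapsed, sizes)
            ctrl_sites = define_binding_sites(
                collapse_adjacent_peaks(ctrl), sizes
            )
            kept, removed = subtract_control(sites, ctrl_sites)
            expected = self._oracle(sig, ctrl, sizes)
            got = sorted(
                (s.chrom, s.strand, s.start, s.end, s.peak) for s in kept
            )
            assert got == sorted(expected)
            assert len(kept) + removed == len(sites)


class TestAssignFeatures:
    def test_site_inside_five_prime_utr(self, plus_gene):
        (fa,), summary = assign_features([_mk_site(150)], [plus_gene])
        assert fa.gene_id == "GP"
        assert fa.feature_types == frozenset({"five_prime_UTR"})
        assert not fa.intergenic

    def test_site_spanning_cds_intron_boundary(self, plus_gene):
        (fa,), _ = assign_features([_mk_site(400)], [plus_gene])
        assert fa.feature_types == frozenset({"CDS", "intron"})

    def test_intergenic_and_antisense(self, plus_gene):
        assigns, summary = assign_features(
            [_mk_site(5000), _mk_site(150, strand="-")], [plus_gene]
        )
        assert all(a.intergenic for a in assigns)
        assert summary.empty

    def test_category_percentages(self, plus_gene, minus_gene):
        # GP gets a 5'UTR site; GM gets 5'UTR and CDS sites
        sites = [_mk_site(150), _mk_site(1750, "-"), _mk_site(1600, "-")]
        _, summary = assign_features(sites, [plus_gene, minus_gene])
        pct = feature_category_percentages(summary)
        assert pct["five_prime_UTR"] == pytest.approx(100.0)
        assert pct["CDS"] == pytest.approx(50.0)
        assert pct["intron"] == pytest.approx(0.0)


@settings(derandomize=True, max_examples=40)
@given(
    starts=hst.lists(hst.integers(0, 30), min_size=0, max_size=30),
    barcodes=hst.lists(hst.sampled_from(["AA", "CC", "GG"]), min_size=0, max_size=30),
)
def test_dedup_idempotent_property(starts, barcodes):
    reads = [
        ReadRecord("chr1", "+", s, b) for s, b in zip(starts, barcodes)
    ]
    once = dedup_reads(reads)
    assert dedup_reads(once) == once
    assert len(once) == len({(r.start, r.barcode) for r in reads})
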