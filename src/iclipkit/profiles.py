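"""Positional metaprofiles of binding sites around genomic anchors.

Offsets are always strand-oriented: 0 is the anchor itself (the TSS, the
first intronic base of a donor, or the first base of a motif match),
positive offsets are downstream (3') of the anchor, negative upstream (5').
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .core import GeneModel, GenomeSequence, Interval, reverse_complement
from .sites import BindingSite, _gene_trees


@dataclass
class DistanceProfile:
    """Histogram of strand-oriented offsets of site peaks to an anchor."""

    anchor_kind: str  # tss | donor | motif
    window: tuple[int, int]
    offsets: Counter = field(default_factory=Counter)

    def add(self, offset: int) -> None:
        lo, hi = self.window
        if lo <= offset <= hi:
            self.offsets[offset] += 1

    def total(self) -> int:
        return sum(self.offsets.values())

    def mass_in(self, lo: int, hi: int) -> float:
        """Fraction of tallied offsets falling inside [lo, hi]."""
        total = self.total()
        if total == 0:
            return float("nan")
        return sum(c for o, c in self.offsets.items() if lo <= o <= hi) / total


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over a stack of equal-width sequences."""

    width: int
    counts: np.ndarray  # shape (4, width), rows A C G T
    n_skipped: np.ndarray  # per-position count of N bases
    n_sequences: int

    BASES = "ACGT"

    def column(self, pos: int) -> dict[str, int]:
        return {b: int(self.counts[i, pos]) for i, b in enumerate(self.BASES)}


def _oriented_offset(strand: str, anchor: int, pos: int) -> int:
    return pos - anchor if strand == "+" else anchor - pos


def distances_to_tss(
    sites: list[BindingSite],
    models: list[GeneModel],
    max_downstream: int = 250,
) -> DistanceProfile:
    """Tally strand-oriented distances from each gene's most-5' TSS to the
    peaks of the sites overlapping that gene, keeping offsets in
    [0, max_downstream]. Sites overlapping no gene are ignored."""
    trees = _gene_trees(models)
    profile = DistanceProfile(anchor_kind="tss", window=(0, max_downstream))
    for s in sites:
        for hit in trees.get((s.chrom, s.strand), IntervalTree())[s.start : s.end]:
            g = models[hit.data]
            profile.add(_oriented_offset(g.strand, g.tss, s.peak))
    return profile


def distances_to_donors(
    sites: list[BindingSite],
    models: list[GeneModel],
    min_exon_len: int = 50,
    window: tuple[int, int] = (-50, 10),
) -> DistanceProfile:
    """Tally site-peak offsets to 5' splice sites (donors) whose upstream
    exon is at least ``min_exon_len`` nt long.

    Offset 0 is the first intronic base; exonic (upstream) positions are
    negative. All same-gene site peaks are compared against every
    qualifying donor of that gene, restricted to ``window``."""
    trees = _gene_trees(models)
    gene_sites: dict[int, list[BindingSite]] = defaultdict(list)
    for s in sites:
        for hit in trees.get((s.chrom, s.strand), IntervalTree())[s.start : s.end]:
            gene_sites[hit.data].append(s)

    profile = DistanceProfile(anchor_kind="donor", window=window)
    for idx, g_sites in gene_sites.items():
        g = models[idx]
        exon_lens = g.donor_upstream_exon_lengths()
        for donor, exon_len in zip(g.donors, exon_lens):
            if exon_len < min_exon_len:
                continue
            for s in g_sites:
                profile.add(_oriented_offset(g.strand, donor, s.peak))
    return profile


def window_matrix(
    sites: list[BindingSite],
    genome: GenomeSequence,
    width: int = 21,
) -> PositionFrequencyMatrix:
    """Stack the ``width``-nt strand-oriented sequences centred on each
    site peak into a position-frequency matrix. Peaks closer than width//2
    to a chromosome end are skipped."""
    if width % 2 == 0:
        raise ValueError("width must be odd")
    half = width // 2
    counts = np.zeros((4, width), dtype=np.int64)
    n_skipped = np.zeros(width, dtype=np.int64)
    n_sequences = 0
    index = {b: i for i, b in enumerate("ACGT")}
    for s in sites:
        start, end = s.peak - half, s.peak + half + 1
        if start < 0 or end > genome.length(s.chrom):
            continue
        seq = genome.fetch(Interval(s.chrom, start, end, s.strand))
        n_sequences += 1
        for pos, base in enumerate(seq):
            if base in index:
                counts[index[base], pos] += 1
            else:
                n_skipped[pos] += 1
    return PositionFrequencyMatrix(
        width=width, counts=counts, n_skipped=n_skipped, n_sequences=n_sequences
    )


def find_motif_occurrences(
    genome: GenomeSequence,
    motif: str,
) -> dict[tuple[str, str], np.ndarray]:
    """Genomic positions of the motif's first base for every strand-specific
    exact match, keyed by (chrom, strand); positions are sorted."""
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    occurrences: dict[tuple[str, str], np.ndarray] = {}
    rc = reverse_complement(motif)
    for chrom in genome.chroms:
        seq = genome.sequence(chrom)
        occurrences[(chrom, "+")] = np.array(_find_all(seq, motif), dtype=np.int64)
        # a '-' strand match at + coordinates [i, i+m) has its first base
        # (5' on '-') at the rightmost genomic coordinate
        minus = [i + len(motif) - 1 for i in _find_all(seq, rc)]
        occurrences[(chrom, "-")] = np.array(sorted(minus), dtype=np.int64)
    return occurrences


def _find_all(seq: str, pattern: str) -> list[int]:
    out, i = [], seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def scan_motif_and_distances(
    sites: list[BindingSite],
    genome: GenomeSequence,
    motif: str = "CAGA",
    window: tuple[int, int] = (-20, 20),
    all_occurrences: bool = False,
) -> DistanceProfile:
    """Offsets of each site peak to its nearest same-strand motif match.

    Offset 0 means the peak coincides with the motif's first base; ties
    between equidistant matches count toward the upstream (5') one, i.e.
    the positive offset. With ``all_occurrences`` every in-window match is
    tallied instead of only the nearest."""
    occ = find_motif_occurrences(genome, motif)
    profile = DistanceProfile(anchor_kind="motif", window=window)
    for s in sites:
        positions = occ.get((s.chrom, s.strand))
        if positions is None or len(positions) == 0:
            continue
        if all_occurrences:
            for p in positions:
                profile.add(_oriented_offset(s.strand, int(p), s.peak))
            continue
        i = int(np.searchsorted(positions, s.peak))
        candidates = []
        if i < len(positions):
            candidates.append(int(positions[i]))
        if i > 0:
            candidates.append(int(positions[i - 1]))
        best = min(
            (
                (abs(s.peak - p), -_oriented_offset(s.strand, p, s.peak), p)
                for p in candidates
            ),
        )
        profile.add(_oriented_offset(s.strand, best[2], s.peak))
    return profile
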