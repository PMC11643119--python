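"""Binding-site definition from crosslink peaks.

The pipeline is: deduplicate reads by (position, random barcode), collapse
runs of immediately adjacent peaks keeping the best-scoring one, extend each
surviving peak by a fixed number of nucleotides on both sides to a 9-nt
binding site, remove signal sites that fall within a fixed distance of a
background-control site, and assign the remainder to gene features.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .core import CODING_FEATURES, GeneModel, Interval, STRANDS


@dataclass(frozen=True)
class ReadRecord:
    """A mapped read reduced to its truncation position and random barcode."""

    chrom: str
    strand: str
    start: int
    barcode: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.barcode:
            raise ValueError("empty barcode")


@dataclass(frozen=True)
class CrosslinkPeak:
    """A single-nucleotide crosslink position with its peak-caller score."""

    chrom: str
    strand: str
    pos: int
    score: float

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class BindingSite:
    """A strand-aware interval of nominal width 9 centred on ``peak``."""

    chrom: str
    strand: str
    start: int
    end: int
    peak: int
    score: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (self.start <= self.peak < self.end):
            raise ValueError(
                f"peak {self.peak} outside [{self.start}, {self.end})"
            )
        # clipping at a chromosome edge is the only way the peak may sit
        # off-centre
        if not self.clipped and self.peak != self.start + (self.end - self.start) // 2:
            raise ValueError("non-clipped binding site must be centred on its peak")

    def __len__(self) -> int:
        return self.end - self.start

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


@dataclass
class FeatureAssignment:
    """Which gene features (if any) one binding site overlaps."""

    site: BindingSite
    gene_id: str | None
    feature_types: frozenset[str]
    intergenic: bool

    def __post_init__(self) -> None:
        if self.intergenic == bool(self.gene_id and self.feature_types):
            raise ValueError("intergenic XOR assigned-gene violated")


def dedup_reads(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Remove PCR duplicates: keep the first read of each
    (chrom, strand, start, barcode) group, preserving input order."""
    seen: set[tuple] = set()
    out = []
    for r in reads:
        key = (r.chrom, r.strand, r.start, r.barcode)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def collapse_adjacent_peaks(peaks: list[CrosslinkPeak]) -> list[CrosslinkPeak]:
    """Group maximal runs of peaks at consecutive positions on one
    chrom/strand and keep only the highest-scoring member of each run.

    Score ties keep the 5'-most peak (smallest position on '+', largest on
    '-'). Two peaks at the identical position are an error: the caller is
    expected to have merged them already.
    """
    by_group: dict[tuple[str, str], list[CrosslinkPeak]] = defaultdict(list)
    for p in peaks:
        by_group[(p.chrom, p.strand)].append(p)

    out: list[CrosslinkPeak] = []
    for (chrom, strand) in sorted(by_group):
        members = sorted(by_group[(chrom, strand)], key=lambda p: p.pos)
        for a, b in zip(members, members[1:]):
            if a.pos == b.pos:
                raise ValueError(
                    f"duplicate peak position {chrom}{strand}:{a.pos}"
                )
        run: list[CrosslinkPeak] = []
        for p in members:
            if run and p.pos == run[-1].pos + 1:
                run.append(p)
            else:
                if run:
                    out.append(_best_of_run(run, strand))
                run = [p]
        if run:
            out.append(_best_of_run(run, strand))
    return out


def _best_of_run(run: list[CrosslinkPeak], strand: str) -> CrosslinkPeak:
    best_score = max(p.score for p in run)
    tied = [p for p in run if p.score == best_score]
    return min(tied, key=lambda p: p.pos) if strand == "+" else max(
        tied, key=lambda p: p.pos
    )


def define_binding_sites(
    peaks: list[CrosslinkPeak],
    chrom_sizes: dict[str, int],
    ext: int = 4,
) -> list[BindingSite]:
    """Extend each peak by ``ext`` nt on both sides into a binding site of
    width 2*ext+1 (9 for the default), clipping at chromosome edges."""
    if ext < 0:
        raise ValueError("ext must be >= 0")
    sites = []
    for p in peaks:
        if p.chrom not in chrom_sizes:
            raise KeyError(f"unknown chromosome {p.chrom!r}")
        size = chrom_sizes[p.chrom]
        if not (0 <= p.pos < size):
            raise ValueError(
                f"peak {p.chrom}:{p.pos} outside chromosome of length {size}"
            )
        start = max(0, p.pos - ext)
        end = min(size, p.pos + ext + 1)
        sites.append(
            BindingSite(
                chrom=p.chrom,
                strand=p.strand,
                start=start,
                end=end,
                peak=p.pos,
                score=p.score,
                clipped=(end - start) != 2 * ext + 1,
            )
        )
    return sites


def subtract_control(
    signal: list[BindingSite],
    control: list[BindingSite],
    window: int = 9,
) -> tuple[list[BindingSite], int]:
    """Remove every signal site whose peak lies within ``window`` nt of a
    same-chrom/strand control-site peak; return (kept, removed_count)."""
    if window < 0:
        raise ValueError("window must be >= 0")
    ctrl_pos: dict[tuple[str, str], list[int]] = defaultdict(list)
    for c in control:
        ctrl_pos[(c.chrom, c.strand)].append(c.peak)
    for v in ctrl_pos.values():
        v.sort()

    kept = []
    for s in signal:
        positions = ctrl_pos.get((s.chrom, s.strand))
        if positions and _min_distance(positions, s.peak) <= window:
            continue
        kept.append(s)
    return kept, len(signal) - len(kept)


def _min_distance(sorted_positions: list[int], pos: int) -> int:
    i = bisect_left(sorted_positions, pos)
    best = math.inf
    if i < len(sorted_positions):
        best = sorted_positions[i] - pos
    if i > 0:
        best = min(best, pos - sorted_positions[i - 1])
    return best


def _gene_trees(
    models: list[GeneModel],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for idx, g in enumerate(models):
        span = g.span()
        trees[(g.chrom, g.strand)][span.start : span.end] = idx
    return trees


def assign_features(
    sites: list[BindingSite],
    models: list[GeneModel],
) -> tuple[list[FeatureAssignment], pd.DataFrame]:
    """Assign each site to every feature type of a same-strand gene it
    overlaps by >=1 nt; sites overlapping no gene are intergenic.

    The per-gene summary has one row per gene with >=1 site, flagging which
    of the four protein-coding categories (5'UTR, CDS, intron, 3'UTR)
    contain a site; a gene may count in several categories.
    """
    trees = _gene_trees(models)
    per_site: list[FeatureAssignment] = []
    gene_hits: dict[str, set[str]] = defaultdict(set)
    gene_nsites: dict[str, int] = defaultdict(int)

    for s in sites:
        hits = trees.get((s.chrom, s.strand), IntervalTree())[s.start : s.end]
        assigned = False
        for hit in sorted(hits, key=lambda h: h.data):
            g = models[hit.data]
            ftypes = set()
            for ftype, iv in g.features:
                if ftype == "exon" and g.biotype == "protein_coding":
                    continue  # coding exons are fully covered by UTR/CDS
                if iv.start < s.end and s.start < iv.end:
                    ftypes.add(ftype)
            if ftypes:
                per_site.append(
                    FeatureAssignment(
                        site=s,
                        gene_id=g.gene_id,
                        feature_types=frozenset(ftypes),
                        intergenic=False,
                    )
                )
                gene_hits[g.gene_id] |= ftypes
                gene_nsites[g.gene_id] += 1
                assigned = True
        if not assigned:
            per_site.append(
                FeatureAssignment(
                    site=s, gene_id=None, feature_types=frozenset(), intergenic=True
                )
            )

    biotype = {g.gene_id: g.biotype for g in models}
    rows = []
    for gene_id in sorted(gene_hits):
        row = {
            "gene_id": gene_id,
            "biotype": biotype[gene_id],
            "n_sites": gene_nsites[gene_id],
        }
        for cat in CODING_FEATURES:
            row[f"has_{cat}"] = cat in gene_hits[gene_id]
        rows.append(row)
    columns = ["gene_id", "biotype", "n_sites"] + [
        f"has_{c}" for c in CODING_FEATURES
    ]
    summary = pd.DataFrame(rows, columns=columns)
    return per_site, summary


def feature_category_percentages(summary: pd.DataFrame) -> dict[str, float]:
    """Percentage of protein-coding target genes with >=1 site per category.

    Denominator is the number of protein-coding genes carrying at least one
    site; a gene may appear in several categories, so the percentages may
    sum to more than 100.
    """
    coding = summary[summary["biotype"] == "protein_coding"]
    n = len(coding)
    if n == 0:
        return {cat: float("nan") for cat in CODING_FEATURES}
    return {
        cat: 100.0 * coding[f"has_{cat}"].sum() / n for cat in CODING_FEATURES
    }


def target_gene_counts(summary: pd.DataFrame) -> dict[str, int]:
    """Count target genes (>=1 site) by biotype."""
    counts = summary["biotype"].value_counts().to_dict()
    return {
        "protein_coding": int(counts.get("protein_coding", 0)),
        "non_coding": int(counts.get("non_coding", 0)),
        "total": int(len(summary)),
    }
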