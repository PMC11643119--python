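"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout. BED is read
natively; GFF3 (1-based inclusive) is converted on read. Readers reject
malformed records with an error naming the offending line instead of
silently repairing them.
"""

from __future__ import annotations

import dataclasses

import gffutils
import pandas as pd

from .core import GeneModel, Interval, STRANDS
from .events import SpliceEvent
from .kmers import KmerEnrichmentResult
from .sites import BindingSite, CrosslinkPeak, ReadRecord

_TX_TYPES = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "snoRNA", "tRNA", "rRNA"}


def _parse_bed6(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 BED fields, got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            try:
                score = float(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            yield lineno, chrom, start, end, name, score, strand


def read_bed_peaks(path, kind: str):
    """Read a BED6 file as crosslink peaks (``kind='peak'``, width-1
    records) or binding sites (``kind='site'``, peak at the interval
    midpoint). File order is preserved."""
    if kind not in ("peak", "site"):
        raise ValueError(f"kind must be 'peak' or 'site', got {kind!r}")
    out = []
    for lineno, chrom, start, end, _name, score, strand in _parse_bed6(path):
        if kind == "peak":
            if end - start != 1:
                raise ValueError(
                    f"{path}:{lineno}: peak record must have width 1, "
                    f"got {end - start}"
                )
            out.append(CrosslinkPeak(chrom=chrom, strand=strand, pos=start, score=score))
        else:
            out.append(
                BindingSite(
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    peak=(start + end) // 2,
                    score=score,
                    clipped=(end - start) != 9,
                )
            )
    return out


def read_bed_reads(path) -> list[ReadRecord]:
    """Read mapped-read records from BED6 with the random barcode in the
    name field."""
    out = []
    for lineno, chrom, start, _end, name, _score, strand in _parse_bed6(path):
        if not name:
            raise ValueError(f"{path}:{lineno}: empty barcode in name field")
        out.append(ReadRecord(chrom=chrom, strand=strand, start=start, barcode=name))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>size")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _choose_representative(tx_ids: list[str], cds_len: dict[str, int]) -> str:
    """Default representative-transcript rule: prefer the ID ending in
    '.1', else the longest CDS, ties broken lexicographically."""
    dot1 = [t for t in tx_ids if t.endswith(".1")]
    if dot1:
        return sorted(dot1)[0]
    return sorted(tx_ids, key=lambda t: (-cds_len.get(t, 0), t))[0]


def read_gff3_models(
    path,
    representative: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Parse a GFF3 annotation into one GeneModel per gene.

    Exactly one representative transcript is kept per gene (a supplied
    ``representative`` mapping wins; the default rule prefers IDs ending in
    '.1', then the longest CDS). Introns are derived as the gaps between
    consecutive exons; donors (first intronic base, 5'->3') and the most-5'
    TSS over all transcripts are computed strand-aware.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        txs = [
            f for f in db.children(gene, level=1) if f.featuretype in _TX_TYPES
        ]
        if not txs:
            raise ValueError(f"gene {gene.id}: no transcripts")
        cds_len = {}
        for t in txs:
            cds_len[t.id] = sum(
                c.end - c.start + 1 for c in db.children(t, featuretype="CDS")
            )
        if representative and gene.id in representative:
            want = representative[gene.id]
            match = [t for t in txs if t.id == want]
            if not match:
                raise ValueError(
                    f"gene {gene.id}: representative transcript {want!r} not found"
                )
            rep = match[0]
        else:
            rep_id = _choose_representative([t.id for t in txs], cds_len)
            rep = next(t for t in txs if t.id == rep_id)

        strand = gene.strand
        if strand not in STRANDS:
            raise ValueError(f"gene {gene.id}: missing strand")
        chrom = gene.seqid

        # most 5' TSS over all transcripts of the gene
        if strand == "+":
            tss = min(t.start for t in txs) - 1
        else:
            tss = max(t.end for t in txs) - 1

        features: list[tuple[str, Interval]] = []
        exons = sorted(
            db.children(rep, featuretype="exon"), key=lambda f: f.start
        )
        if not exons:
            raise ValueError(f"gene {gene.id}: transcript {rep.id} has no exons")
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"gene {gene.id}: overlapping exons in transcript {rep.id}"
                )
        exon_ivs = [
            Interval(chrom, e.start - 1, e.end, strand) for e in exons
        ]
        features += [("exon", iv) for iv in exon_ivs]
        for ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
            for f in db.children(rep, featuretype=ftype):
                features.append(
                    (ftype, Interval(chrom, f.start - 1, f.end, strand))
                )
        intron_ivs = [
            Interval(chrom, a.end, b.start, strand)
            for a, b in zip(exon_ivs, exon_ivs[1:])
        ]
        features += [("intron", iv) for iv in intron_ivs]

        if strand == "+":
            donors = [iv.start for iv in intron_ivs]
        else:
            donors = [iv.end - 1 for iv in reversed(intron_ivs)]

        biotype = "protein_coding" if cds_len.get(rep.id, 0) > 0 else "non_coding"
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=chrom,
                strand=strand,
                biotype=biotype,
                tss=tss,
                representative_tx_id=rep.id,
                features=features,
                donors=donors,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "gene",
    "coord",
    "strand",
    "type",
    "psi_a",
    "psi_b",
    "delta_psi",
    "probability",
    "junctions_detected",
    "reads_control",
    "reads_test",
]


def _parse_coord(coord: str, strand: str) -> Interval:
    chrom, _, rest = coord.partition(":")
    start, _, end = rest.partition("-")
    return Interval(chrom, int(start), int(end), strand)


def _parse_bools(text: str) -> tuple[bool, bool]:
    parts = [p.strip().lower() for p in str(text).split(",")]
    if len(parts) != 2 or any(p not in ("true", "false") for p in parts):
        raise ValueError(f"expected two comma-separated booleans, got {text!r}")
    return tuple(p == "true" for p in parts)  # type: ignore[return-value]


def _parse_ints(text) -> tuple[int, ...]:
    text = str(text).strip()
    if not text:
        return ()
    return tuple(int(p) for p in text.split(","))


def read_event_table(path) -> list[SpliceEvent]:
    """Read a differential-splicing event TSV (delta-style schema) into
    SpliceEvent records, recomputing and checking dPSI on the way in."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                SpliceEvent(
                    gene_id=row["gene"],
                    iv=_parse_coord(row["coord"], row["strand"]),
                    etype=row["type"],
                    psi_a=float(row["psi_a"]),
                    psi_b=float(row["psi_b"]),
                    delta_psi=float(row["delta_psi"]),
                    probability=float(row["probability"]),
                    junctions_detected=_parse_bools(row["junctions_detected"]),
                    reads_control=_parse_ints(row["reads_control"]),
                    reads_test=_parse_ints(row["reads_test"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _event_row(e: SpliceEvent) -> list[str]:
    return [
        e.gene_id,
        f"{e.iv.chrom}:{e.iv.start}-{e.iv.end}",
        e.iv.strand,
        e.etype,
        repr(e.psi_a),
        repr(e.psi_b),
        repr(e.delta_psi),
        repr(e.probability),
        ",".join(str(b).lower() for b in e.junctions_detected),
        ",".join(str(r) for r in e.reads_control),
        ",".join(str(r) for r in e.reads_test),
    ]


def write_table(records: list, path, columns: list[str] | None = None) -> None:
    """Write a homogeneous result list as TSV (BED6 for binding sites and
    peaks) with a deterministic column order; read-after-write round-trips.

    For an empty list ``columns`` supplies the header to write.
    """
    with open(path, "w") as fh:
        if not records:
            if columns:
                fh.write("\t".join(columns) + "\n")
            return
        first = records[0]
        if isinstance(first, BindingSite):
            for i, s in enumerate(records):
                fh.write(
                    "\t".join(
                        [s.chrom, str(s.start), str(s.end), f"site_{i}",
                         repr(s.score), s.strand]
                    )
                    + "\n"
                )
        elif isinstance(first, CrosslinkPeak):
            for i, p in enumerate(records):
                fh.write(
                    "\t".join(
                        [p.chrom, str(p.pos), str(p.pos + 1), f"peak_{i}",
                         repr(p.score), p.strand]
                    )
                    + "\n"
                )
        elif isinstance(first, KmerEnrichmentResult):
            fh.write("kmer\tobserved\tnull_mean\tnull_sd\tz\n")
            for r in records:
                z = "NA" if r.z is None else repr(r.z)
                fh.write(
                    f"{r.kmer}\t{r.observed}\t{repr(r.null_mean)}\t"
                    f"{repr(r.null_sd)}\t{z}\n"
                )
        elif isinstance(first, SpliceEvent):
            fh.write("\t".join(EVENT_COLUMNS) + "\n")
            for e in records:
                fh.write("\t".join(_event_row(e)) + "\n")
        elif dataclasses.is_dataclass(first):
            names = [f.name for f in dataclasses.fields(first)]
            fh.write("\t".join(names) + "\n")
            for r in records:
                fh.write(
                    "\t".join(str(getattr(r, n)) for n in names) + "\n"
                )
        else:
            raise TypeError(f"cannot serialize records of type {type(first)}")
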