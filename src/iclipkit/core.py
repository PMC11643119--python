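"""Core genomic value types shared by every analysis stage.

All coordinates are 0-based, half-open on the forward strand, regardless of
the file format they came from (GFF3 is converted on read, BED is native).
Strand never changes the coordinates themselves; it only controls the
orientation of sequence extraction and of strand-oriented offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-")
DNA_BASES = "ACGT"

#: Feature categories a binding site can be assigned to within a
#: protein-coding gene; non-coding genes only expose exon/intron.
CODING_FEATURES = ("five_prime_UTR", "CDS", "intron", "three_prime_UTR")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True iff the two intervals share >=1 nt on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """Uppercase DNA sequences keyed by chromosome name.

    Lookups beyond a sequence's length, or on an unknown chromosome, are
    errors rather than silently truncated.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in seqs.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{chrom}: non-ACGTN characters {sorted(bad)}")
            self._seqs[chrom] = seq

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._seqs[chrom]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, iv: Interval) -> str:
        """Strand-oriented sequence of *iv* (reverse-complemented for '-')."""
        if iv.chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} "
                f"length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if iv.strand == "-" else sub

    def mutate(self, chrom: str, pos: int, replacement: str) -> None:
        """Overwrite bases in place (used by the simulator to plant motifs)."""
        seq = self.sequence(chrom)
        if pos < 0 or pos + len(replacement) > len(seq):
            raise ValueError("replacement outside chromosome bounds")
        self._seqs[chrom] = seq[:pos] + replacement.upper() + seq[pos + len(replacement):]

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._seqs):
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def extract_sequence(genome: GenomeSequence, iv: Interval) -> str:
    """Strand-specific sequence extraction (module-level spelling of fetch)."""
    return genome.fetch(iv)


@dataclass
class GeneModel:
    """One gene reduced to a single representative transcript.

    ``features`` holds (feature_type, Interval) pairs where feature_type is
    one of five_prime_UTR / CDS / intron / three_prime_UTR / exon. ``donors``
    lists the first intronic base of each intron in 5'->3' transcript order.
    ``tss`` is the most 5' transcript start observed for the gene (0-based).
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str  # protein_coding | non_coding
    tss: int
    representative_tx_id: str
    features: list[tuple[str, Interval]] = field(default_factory=list)
    donors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.biotype not in ("protein_coding", "non_coding"):
            raise ValueError(f"invalid biotype {self.biotype!r}")
        for ftype, iv in self.features:
            if iv.chrom != self.chrom or iv.strand != self.strand:
                raise ValueError(
                    f"{self.gene_id}: feature {ftype} on {iv.chrom}{iv.strand} "
                    f"does not match gene {self.chrom}{self.strand}"
                )
        if len(self.donors) != len(self.introns()):
            raise ValueError(
                f"{self.gene_id}: {len(self.donors)} donors for "
                f"{len(self.introns())} introns"
            )

    def _of_type(self, ftype: str) -> list[Interval]:
        return sorted(
            (iv for t, iv in self.features if t == ftype), key=lambda i: i.start
        )

    def exons(self) -> list[Interval]:
        return self._of_type("exon")

    def introns(self) -> list[Interval]:
        return self._of_type("intron")

    def cds(self) -> list[Interval]:
        return self._of_type("CDS")

    def span(self) -> Interval:
        exons = self.exons()
        if not exons:
            raise ValueError(f"{self.gene_id}: no exons")
        return Interval(self.chrom, exons[0].start, exons[-1].end, self.strand)

    def transcript_order(self, ivs: list[Interval]) -> list[Interval]:
        """Intervals in 5'->3' transcript order for this gene's strand."""
        ivs = sorted(ivs, key=lambda i: i.start)
        return ivs if self.strand == "+" else ivs[::-1]

    def donor_upstream_exon_lengths(self) -> list[int]:
        """Length of the exon immediately 5' of each donor, donor order."""
        exons = self.transcript_order(self.exons())
        return [len(exons[i]) for i in range(len(self.donors))]

    def mature_sequence(self, genome: GenomeSequence) -> str:
        """Spliced (exonic) transcript sequence, 5'->3'."""
        parts = [genome.fetch(e) for e in self.transcript_order(self.exons())]
        return "".join(parts)
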