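"""Synthetic genomes, crosslink data, and event tables with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: crosslink peaks concentrated near transcription start sites and in
a fixed band upstream of 5' splice sites, binding sequences enriched in a
planted motif (CAGA by default) and in CU-rich composition over an i.i.d.
uniform-ACGT background, a uniform background control, PCR-duplicated
reads, and differential-splicing event tables with per-type direction
biases (intron retention promoted, exitron splicing enhanced).

Ground truth is returned as a sidecar structure (and written as JSON),
never encoded in record names.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import GeneModel, GenomeSequence, Interval, reverse_complement
from .events import EVENT_TYPES, SpliceEvent
from .sites import CrosslinkPeak, ReadRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults encode the study conditions."""

    # genome / annotation: ~3 sites per target gene at the default peak
    # count, matching the scale of a small iCLIP study
    n_genes: int = 300
    n_chroms: int = 2
    frac_noncoding: float = 0.2
    utr5_len: tuple[int, int] = (60, 200)
    n_cds_exons: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (90, 240)
    intron_len: tuple[int, int] = (80, 200)
    utr3_len: tuple[int, int] = (80, 200)
    intergenic_gap: tuple[int, int] = (200, 600)
    # crosslink data
    n_signal_peaks: int = 1000
    control_rate: float = 0.08
    motif: str = "CAGA"
    frac_motif_sites: float = 0.2
    frac_cu_rich_sites: float = 0.3
    tss_bias_weight: float = 0.35
    tss_offset_scale: float = 60.0
    tss_max_offset: int = 250
    donor_band: tuple[int, int] = (-30, -25)
    donor_bias_weight: float = 0.25
    pcr_duplication_rate: float = 0.3
    mean_reads_per_peak: float = 2.0
    barcode_len: int = 6
    # differential splicing
    event_counts: dict = field(
        default_factory=lambda: {"RI": 200, "EI": 200, "CE": 60, "AA": 42, "AD": 30}
    )
    direction_bias: dict = field(
        default_factory=lambda: {
            "RI": 0.762, "EI": 0.298, "CE": 0.5, "AA": 0.5, "AD": 0.5
        }
    )
    n_null_events: int = 150
    dpsi_range: tuple[float, float] = (0.1, 0.45)
    n_samples: int = 3
    seed: int = 17

    def __post_init__(self) -> None:
        fracs = {
            "frac_noncoding": self.frac_noncoding,
            "control_rate": self.control_rate,
            "frac_motif_sites": self.frac_motif_sites,
            "frac_cu_rich_sites": self.frac_cu_rich_sites,
            "tss_bias_weight": self.tss_bias_weight,
            "donor_bias_weight": self.donor_bias_weight,
            "pcr_duplication_rate": self.pcr_duplication_rate,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_motif_sites + self.tss_bias_weight + self.donor_bias_weight > 1:
            raise ValueError("peak-class weights sum to more than 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for t in self.event_counts:
            if t not in EVENT_TYPES:
                raise ValueError(f"unknown event type {t!r}")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over ACGT")


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    models: list[GeneModel]

    def chrom_sizes(self) -> dict[str, int]:
        return self.genome.chrom_sizes()

    def transcripts(self) -> dict[str, str]:
        """Mature (spliced) sequence per representative transcript, taken
        from the *current* genome (after any motif planting)."""
        return {
            g.representative_tx_id: g.mature_sequence(self.genome)
            for g in self.models
        }


@dataclass
class SimulatedClip:
    signal_peaks: list[CrosslinkPeak]
    control_peaks: list[CrosslinkPeak]
    reads: list[ReadRecord]
    truth: dict


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _gene_segments(cfg: SimConfig, rng, coding: bool) -> list[tuple[str, int]]:
    """(label, length) in transcript (5'->3') order."""
    if coding:
        segs = [("five_prime_UTR", int(rng.integers(*cfg.utr5_len)))]
        n_ex = int(rng.integers(cfg.n_cds_exons[0], cfg.n_cds_exons[1] + 1))
        for i in range(n_ex):
            if i:
                segs.append(("intron", int(rng.integers(*cfg.intron_len))))
            segs.append(("CDS", int(rng.integers(*cfg.exon_len))))
        segs.append(("three_prime_UTR", int(rng.integers(*cfg.utr3_len))))
    else:
        segs = [("nc_exon", int(rng.integers(*cfg.exon_len)))]
        segs.append(("intron", int(rng.integers(*cfg.intron_len))))
        segs.append(("nc_exon", int(rng.integers(*cfg.exon_len))))
    return segs


def make_genome(cfg: SimConfig) -> SimulatedGenome:
    """Pack non-overlapping genes (both strands, coding and non-coding)
    onto ``n_chroms`` chromosomes of i.i.d. uniform ACGT sequence."""
    rng = _rng(cfg, 0)
    models: list[GeneModel] = []
    chrom_cursors = {f"chr{i + 1}": int(rng.integers(*cfg.intergenic_gap))
                     for i in range(cfg.n_chroms)}
    chrom_names = list(chrom_cursors)

    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= cfg.frac_noncoding
        segs = _gene_segments(cfg, rng, coding)
        genomic = segs if strand == "+" else segs[::-1]

        start = chrom_cursors[chrom]
        gene_id = f"G{gi + 1:04d}"
        tx_id = f"{gene_id}.1"
        features: list[tuple[str, Interval]] = []
        pos = start
        for label, length in genomic:
            iv = Interval(chrom, pos, pos + length, strand)
            if label == "nc_exon":
                features.append(("exon", iv))
            else:
                features.append((label, iv))
            pos += length
        end = pos
        chrom_cursors[chrom] = end + int(rng.integers(*cfg.intergenic_gap))

        # exons = maximal runs of adjacent non-intron segments
        exonic = sorted(
            (iv for t, iv in features if t != "intron"), key=lambda i: i.start
        )
        exons: list[Interval] = []
        for iv in exonic:
            if exons and exons[-1].end == iv.start:
                exons[-1] = Interval(chrom, exons[-1].start, iv.end, strand)
            else:
                exons.append(iv)
        features = [(t, iv) for t, iv in features if t != "exon" or not coding]
        if coding:
            features += [("exon", iv) for iv in exons]
        else:
            features = [(t, iv) for t, iv in features if t != "exon"]
            features += [("exon", iv) for iv in exons]

        introns = sorted(
            (iv for t, iv in features if t == "intron"), key=lambda i: i.start
        )
        if strand == "+":
            donors = [iv.start for iv in introns]
            tss = start
        else:
            donors = [iv.end - 1 for iv in reversed(introns)]
            tss = end - 1

        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                biotype="protein_coding" if coding else "non_coding",
                tss=tss,
                representative_tx_id=tx_id,
                features=features,
                donors=donors,
            )
        )

    seqs = {
        chrom: _rand_seq(rng, cursor + int(rng.integers(*cfg.intergenic_gap)))
        for chrom, cursor in chrom_cursors.items()
    }
    return SimulatedGenome(genome=GenomeSequence(seqs), models=models)


def _exonic_position(rng, gene: GeneModel, margin: int = 6) -> int | None:
    exons = [e for e in gene.exons() if len(e) > 2 * margin]
    if not exons:
        return None
    e = exons[int(rng.integers(0, len(exons)))]
    return int(rng.integers(e.start + margin, e.end - margin))


def simulate_clip(cfg: SimConfig, sim: SimulatedGenome) -> SimulatedClip:
    """Generate signal/control crosslink peaks and barcode-tagged reads.

    Signal peak positions are a mixture over peak classes: motif-planted
    (the genome is mutated so the peak sits on the motif's first base),
    TSS-proximal, donor-band, and uniform-exonic; a fraction of non-motif
    peaks get a CU-rich 9-nt window written around them. Control peaks are
    uniform over exonic positions.
    """
    rng = _rng(cfg, 1)
    genome, models = sim.genome, sim.models
    residual = 1.0 - cfg.frac_motif_sites - cfg.tss_bias_weight - cfg.donor_bias_weight
    weights = [cfg.frac_motif_sites, cfg.tss_bias_weight,
               cfg.donor_bias_weight, residual]
    classes = ["motif", "tss", "donor", "uniform"]
    donor_genes = [
        g for g in models
        if any(l >= 50 for l in g.donor_upstream_exon_lengths())
    ]

    taken: set[tuple[str, str, int]] = set()
    mutated: set[tuple[str, int]] = set()  # bases already overwritten
    peaks: list[CrosslinkPeak] = []
    peak_truth: list[dict] = []
    m = len(cfg.motif)

    def _plant(chrom: str, start: int, replacement: str) -> bool:
        span = {(chrom, i) for i in range(start, start + len(replacement))}
        if span & mutated:
            return False  # never destroy an earlier plant
        genome.mutate(chrom, start, replacement)
        mutated.update(span)
        return True

    for _ in range(cfg.n_signal_peaks):
        cls = classes[int(rng.choice(4, p=weights))]
        placed = False
        for _attempt in range(25):
            g = models[int(rng.integers(0, len(models)))]
            if cls == "motif":
                pos = _exonic_position(rng, g, margin=m + 5)
                if pos is None:
                    continue
            elif cls == "tss":
                off = min(int(rng.exponential(cfg.tss_offset_scale)),
                          cfg.tss_max_offset)
                pos = g.tss + off if g.strand == "+" else g.tss - off
            elif cls == "donor":
                if not donor_genes:
                    continue
                g = donor_genes[int(rng.integers(0, len(donor_genes)))]
                ok = [
                    d for d, l in zip(g.donors, g.donor_upstream_exon_lengths())
                    if l >= 50
                ]
                d = ok[int(rng.integers(0, len(ok)))]
                off = int(rng.integers(cfg.donor_band[0], cfg.donor_band[1] + 1))
                pos = d + off if g.strand == "+" else d - off
            else:
                pos = _exonic_position(rng, g)
                if pos is None:
                    continue
            size = genome.length(g.chrom)
            if not (m + 5 <= pos < size - m - 5):
                continue
            key = (g.chrom, g.strand, pos)
            if key in taken:
                continue
            if cls == "motif":
                if g.strand == "+":
                    ok = _plant(g.chrom, pos, cfg.motif)
                else:
                    ok = _plant(g.chrom, pos - m + 1,
                                reverse_complement(cfg.motif))
                if not ok:
                    continue
            elif rng.random() < cfg.frac_cu_rich_sites:
                window = "".join(
                    _BASES[rng.choice(4, size=9, p=[0.05, 0.45, 0.05, 0.45])]
                )
                planted = window if g.strand == "+" else reverse_complement(window)
                if not _plant(g.chrom, pos - 4, planted):
                    continue
                cls = cls + "+cu_rich"
            taken.add(key)
            score = float(np.round(rng.gamma(2.0, 2.0) + 0.1, 3))
            peaks.append(
                CrosslinkPeak(chrom=g.chrom, strand=g.strand, pos=pos, score=score)
            )
            peak_truth.append(
                {"chrom": g.chrom, "strand": g.strand, "pos": pos,
                 "klass": cls, "gene_id": g.gene_id}
            )
            placed = True
            break
        if not placed:
            continue

    n_control = int(round(cfg.control_rate * len(peaks)))
    control: list[CrosslinkPeak] = []
    ctrl_taken: set[tuple[str, str, int]] = set()
    while len(control) < n_control:
        g = models[int(rng.integers(0, len(models)))]
        pos = _exonic_position(rng, g)
        if pos is None:
            continue
        key = (g.chrom, g.strand, pos)
        if key in ctrl_taken:
            continue
        ctrl_taken.add(key)
        score = float(np.round(rng.gamma(1.5, 1.0) + 0.1, 3))
        control.append(
            CrosslinkPeak(chrom=g.chrom, strand=g.strand, pos=pos, score=score)
        )

    reads: list[ReadRecord] = []
    n_unique = 0
    duplicate_groups = 0
    for p in peaks:
        k = 1 + int(rng.poisson(cfg.mean_reads_per_peak))
        # distinct barcodes within a peak, so unique reads never collide
        codes = rng.choice(4 ** cfg.barcode_len, size=k, replace=False)
        for code in codes:
            barcode = "".join(
                "ACGT"[(int(code) >> (2 * j)) & 3] for j in range(cfg.barcode_len)
            )
            copies = 1
            if rng.random() < cfg.pcr_duplication_rate:
                copies += 1 + int(rng.poisson(1.0))
                duplicate_groups += 1
            n_unique += 1
            for _c in range(copies):
                reads.append(
                    ReadRecord(chrom=p.chrom, strand=p.strand, start=p.pos,
                               barcode=barcode)
                )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    truth = {
        "peaks": peak_truth,
        "n_signal_peaks": len(peaks),
        "n_control_peaks": len(control),
        "n_reads_total": len(reads),
        "n_reads_unique": n_unique,
        "n_duplicate_groups": duplicate_groups,
    }
    return SimulatedClip(
        signal_peaks=peaks, control_peaks=control, reads=reads, truth=truth
    )


def simulate_events(
    cfg: SimConfig, models: list[GeneModel]
) -> tuple[list[SpliceEvent], dict]:
    """Event table with planted significant events (per-type counts and
    direction biases from the config) plus null events built to fail each
    significance-filter clause."""
    rng = _rng(cfg, 2)
    events: list[SpliceEvent] = []
    truth_planted: list[dict] = []
    lo, hi = cfg.dpsi_range

    def _interval(g: GeneModel) -> Interval:
        span = g.span()
        length = int(rng.integers(60, 200))
        start = int(rng.integers(span.start, max(span.start + 1, span.end - length)))
        return Interval(g.chrom, start, start + length, g.strand)

    for etype in EVENT_TYPES:
        for _ in range(int(cfg.event_counts.get(etype, 0))):
            g = models[int(rng.integers(0, len(models)))]
            up = rng.random() < cfg.direction_bias.get(etype, 0.5)
            mag = float(rng.uniform(lo, hi))
            if up:
                psi_a = round(float(rng.uniform(0.02, 0.98 - mag)), 6)
                psi_b = round(psi_a + mag, 6)
            else:
                psi_a = round(float(rng.uniform(0.02 + mag, 0.98)), 6)
                psi_b = round(psi_a - mag, 6)
            reads_c = tuple(int(1 + rng.poisson(6)) for _ in range(cfg.n_samples))
            reads_t = tuple(int(1 + rng.poisson(6)) for _ in range(cfg.n_samples))
            ev = SpliceEvent(
                gene_id=g.gene_id,
                iv=_interval(g),
                etype=etype,
                psi_a=psi_a,
                psi_b=psi_b,
                delta_psi=round(psi_b - psi_a, 9),
                probability=float(np.round(rng.uniform(0.9, 1.0), 6)),
                junctions_detected=(True, True),
                reads_control=reads_c,
                reads_test=reads_t,
            )
            events.append(ev)
            truth_planted.append(
                {"index": len(events) - 1, "type": etype, "up": bool(up)}
            )

    null_modes = ["low_prob", "low_dpsi", "missing_junction", "ri_no_reads"]
    null_indices = []
    for i in range(cfg.n_null_events):
        mode = null_modes[i % len(null_modes)]
        g = models[int(rng.integers(0, len(models)))]
        etype = "AA" if mode == "missing_junction" else (
            "RI" if mode == "ri_no_reads"
            else EVENT_TYPES[int(rng.integers(0, len(EVENT_TYPES)))]
        )
        mag = float(rng.uniform(lo, hi))
        prob = float(np.round(rng.uniform(0.9, 1.0), 6))
        junctions = (True, True)
        reads_c = tuple(int(1 + rng.poisson(4)) for _ in range(cfg.n_samples))
        reads_t = tuple(int(1 + rng.poisson(4)) for _ in range(cfg.n_samples))
        if mode == "low_prob":
            prob = float(np.round(rng.uniform(0.0, 0.89), 6))
        elif mode == "low_dpsi":
            mag = float(rng.uniform(0.0, 0.099))
        elif mode == "missing_junction":
            junctions = (True, False)
        else:  # ri_no_reads: a zero in some control and some test sample
            reads_c = (0,) + reads_c[1:]
            reads_t = reads_t[:-1] + (0,)
        psi_a = round(float(rng.uniform(0.02 + mag, 0.98)), 6)
        psi_b = round(psi_a - mag, 6)
        events.append(
            SpliceEvent(
                gene_id=g.gene_id,
                iv=_interval(g),
                etype=etype,
                psi_a=psi_a,
                psi_b=psi_b,
                delta_psi=round(psi_b - psi_a, 9),
                probability=prob,
                junctions_detected=junctions,
                reads_control=reads_c,
                reads_test=reads_t,
            )
        )
        null_indices.append(len(events) - 1)

    truth = {
        "planted": truth_planted,
        "null_indices": null_indices,
        "direction_bias": dict(cfg.direction_bias),
        "event_counts": {t: int(c) for t, c in cfg.event_counts.items()},
    }
    return events, truth


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_gff3(models: list[GeneModel], path) -> None:
    """Serialize gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            span = g.span()
            tx_type = "mRNA" if g.biotype == "protein_coding" else "ncRNA"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\t{tx_type}\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.representative_tx_id};Parent={g.gene_id}\n"
            )
            for ftype in ("exon", "five_prime_UTR", "CDS", "three_prime_UTR"):
                for iv in g._of_type(ftype):
                    fh.write(
                        f"{g.chrom}\tsim\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{g.strand}\t.\tParent={g.representative_tx_id}\n"
                    )


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_transcript_fasta(transcripts: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tx in sorted(transcripts):
            fh.write(f">{tx}\n")
            seq = transcripts[tx]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_simulation(cfg: SimConfig, outdir) -> dict:
    """Run the full generator and write every artifact under ``outdir``.

    Returns a manifest of the written paths. Byte-identical across runs for
    the same config (seed included)."""
    import os

    from .io import write_table

    os.makedirs(outdir, exist_ok=True)
    sim = make_genome(cfg)
    clip = simulate_clip(cfg, sim)  # mutates the genome (motif planting)
    events, ev_truth = simulate_events(cfg, sim.models)

    paths = {
        "genome_fasta": os.path.join(outdir, "genome.fa"),
        "gff": os.path.join(outdir, "annotation.gff3"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        "transcripts_fasta": os.path.join(outdir, "transcripts.fa"),
        "signal_bed": os.path.join(outdir, "signal_peaks.bed"),
        "control_bed": os.path.join(outdir, "control_peaks.bed"),
        "reads_bed": os.path.join(outdir, "reads.bed"),
        "events_tsv": os.path.join(outdir, "events.tsv"),
        "truth_json": os.path.join(outdir, "truth.json"),
    }
    sim.genome.to_fasta(paths["genome_fasta"])
    write_gff3(sim.models, paths["gff"])
    write_chrom_sizes(sim.chrom_sizes(), paths["chrom_sizes"])
    write_transcript_fasta(sim.transcripts(), paths["transcripts_fasta"])
    write_table(clip.signal_peaks, paths["signal_bed"])
    write_table(clip.control_peaks, paths["control_bed"])
    with open(paths["reads_bed"], "w") as fh:
        for r in clip.reads:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.start + 1}\t{r.barcode}\t0\t{r.strand}\n"
            )
    write_table(events, paths["events_tsv"])
    truth = {"clip": clip.truth, "events": ev_truth, "config": asdict(cfg)}
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
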