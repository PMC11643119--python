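"""End-to-end orchestration: sites -> kmers -> profiles -> events -> overlap.

A run is driven by a RunConfig (optionally loaded from YAML); every run
writes its outputs plus a manifest recording the resolved parameter set,
the seed, and a SHA-256 checksum of every output file, so a run can be
verified to reproduce bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import events as ev
from . import io as iio
from . import kmers as km
from . import profiles as pr
from . import setstats as ss
from . import sites as st
from .core import GenomeSequence

log = logging.getLogger("iclipkit")

ALL_STAGES = ("sites", "kmers", "profiles", "events", "overlap")


@dataclass
class RunConfig:
    """Validated parameter set for a pipeline run."""

    out_dir: str
    # inputs
    genome_fasta: str | None = None
    gff: str | None = None
    chrom_sizes: str | None = None
    signal_bed: str | None = None
    control_bed: str | None = None
    reads_bed: str | None = None
    transcripts_fasta: str | None = None
    events_tsv: str | None = None
    gene_list_a: str | None = None
    gene_list_b: str | None = None
    universe_list: str | None = None
    # stage parameters
    ext: int = 4
    window: int = 9
    k: int = 6
    iters: int = 1000
    min_exon_len: int = 50
    tss_max: int = 250
    min_prob: float = 0.9
    min_dpsi: float = 0.1
    motif: str = "CAGA"
    pfm_width: int = 21
    donor_window: tuple[int, int] = (-50, 10)
    extraction_band: tuple[int, int] = (-35, -20)
    motif_window: tuple[int, int] = (-20, 20)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = [
            (self.ext >= 0, "ext must be >= 0"),
            (self.window >= 0, "window must be >= 0"),
            (self.k >= 1, "k must be >= 1"),
            (self.iters >= 1, "iters must be >= 1"),
            (self.min_exon_len >= 0, "min_exon_len must be >= 0"),
            (self.tss_max >= 0, "tss_max must be >= 0"),
            (0.0 <= self.min_prob <= 1.0, "min_prob must be in [0, 1]"),
            (self.min_dpsi >= 0.0, "min_dpsi must be >= 0"),
            (self.pfm_width % 2 == 1, "pfm_width must be odd"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("donor_window", "extraction_band", "motif_window", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_profile(profile: pr.DistanceProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tcount\n")
        for off in sorted(profile.offsets):
            fh.write(f"{off}\t{profile.offsets[off]}\n")


def _write_pfm(pfm: pr.PositionFrequencyMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tN_skipped\n")
        for pos in range(pfm.width):
            col = pfm.column(pos)
            fh.write(
                f"{pos}\t{col['A']}\t{col['C']}\t{col['G']}\t{col['T']}\t"
                f"{int(pfm.n_skipped[pos])}\n"
            )


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the manifest.

    Missing input files abort before any stage runs.
    """
    logging.basicConfig(level=config.log_level)
    needed = {
        "sites": ["signal_bed", "chrom_sizes", "gff"],
        "kmers": ["signal_bed", "chrom_sizes", "gff", "genome_fasta"],
        "profiles": ["signal_bed", "chrom_sizes", "gff", "genome_fasta"],
        "events": ["events_tsv"],
        "overlap": [],
    }
    for stage in config.stages:
        for attr in needed[stage]:
            path = getattr(config, attr)
            if path is None or not os.path.exists(path):
                raise FileNotFoundError(
                    f"stage {stage!r} requires input {attr!r} "
                    f"({path!r} not found)"
                )

    os.makedirs(config.out_dir, exist_ok=True)
    params = dataclasses.asdict(config)
    log.info("resolved parameters: %s", json.dumps(params, sort_keys=True, default=str))
    outputs: dict[str, str] = {}
    report: dict = {}

    models = iio.read_gff3_models(config.gff) if config.gff else []
    genome = (
        GenomeSequence.from_fasta(config.genome_fasta)
        if config.genome_fasta
        else None
    )

    kept_sites: list[st.BindingSite] = []
    assignments: list[st.FeatureAssignment] = []
    summary = None

    if "sites" in config.stages:
        sizes = iio.read_chrom_sizes(config.chrom_sizes)
        if config.reads_bed:
            reads = iio.read_bed_reads(config.reads_bed)
            unique = st.dedup_reads(reads)
            report["reads_total"] = len(reads)
            report["reads_unique"] = len(unique)
        signal = st.collapse_adjacent_peaks(
            iio.read_bed_peaks(config.signal_bed, kind="peak")
        )
        sig_sites = st.define_binding_sites(signal, sizes, ext=config.ext)
        if config.control_bed:
            control = st.collapse_adjacent_peaks(
                iio.read_bed_peaks(config.control_bed, kind="peak")
            )
            ctrl_sites = st.define_binding_sites(control, sizes, ext=config.ext)
            kept_sites, removed = st.subtract_control(
                sig_sites, ctrl_sites, window=config.window
            )
        else:
            kept_sites, removed = sig_sites, 0
        assignments, summary = st.assign_features(kept_sites, models)
        report["sites"] = {
            "n_signal_peaks": len(signal),
            "n_signal_sites": len(sig_sites),
            "n_removed_by_control": removed,
            "n_kept_sites": len(kept_sites),
            "target_genes": st.target_gene_counts(summary),
            "feature_percentages": st.feature_category_percentages(summary),
        }
        sites_path = os.path.join(config.out_dir, "sites.bed")
        iio.write_table(kept_sites, sites_path)
        outputs["sites.bed"] = sites_path
        summary_path = os.path.join(config.out_dir, "gene_summary.tsv")
        summary.to_csv(summary_path, sep="\t", index=False)
        outputs["gene_summary.tsv"] = summary_path

    if "kmers" in config.stages:
        usable = [s for s in kept_sites if len(s) == 9]
        seqs = [genome.fetch(s.interval()) for s in usable]
        observed = km.count_kmers(seqs, k=config.k)
        rep_tx = {g.gene_id: g.representative_tx_id for g in models}
        site_gene: dict[tuple, str] = {}
        for a in assignments:
            if not a.intergenic:
                key = (a.site.chrom, a.site.strand, a.site.start)
                site_gene.setdefault(key, a.gene_id)
        transcripts = {
            g.representative_tx_id: g.mature_sequence(genome) for g in models
        }
        null_sites, null_tx = [], []
        for s in usable:
            gene = site_gene.get((s.chrom, s.strand, s.start))
            if gene is None:
                continue
            null_sites.append(s)
            null_tx.append(rep_tx[gene])
        null = km.resampling_null(
            null_sites, null_tx, transcripts,
            n_iter=config.iters, k=config.k, seed=config.seed,
        )
        results = km.kmer_zscores(observed, null)
        kmer_path = os.path.join(config.out_dir, "kmers.tsv")
        iio.write_table(results, kmer_path)
        outputs["kmers.tsv"] = kmer_path
        top = [r for r in results if r.z is not None][:5]
        report["kmers"] = {
            "n_site_sequences": len(seqs),
            "n_null_sites": len(null_sites),
            "top_kmers": [(r.kmer, round(r.z, 3)) for r in top],
        }

    if "profiles" in config.stages:
        tss = pr.distances_to_tss(kept_sites, models, max_downstream=config.tss_max)
        donors = pr.distances_to_donors(
            kept_sites, models,
            min_exon_len=config.min_exon_len, window=config.donor_window,
        )
        motif = pr.scan_motif_and_distances(
            kept_sites, genome, motif=config.motif, window=config.motif_window
        )
        band_lo, band_hi = config.extraction_band
        band_sites = _sites_in_donor_band(
            kept_sites, models, config.min_exon_len, (band_lo, band_hi)
        )
        pfm = pr.window_matrix(band_sites, genome, width=config.pfm_width)
        for name, prof in (("tss", tss), ("donor", donors), ("motif", motif)):
            path = os.path.join(config.out_dir, f"profile_{name}.tsv")
            _write_profile(prof, path)
            outputs[f"profile_{name}.tsv"] = path
        pfm_path = os.path.join(config.out_dir, "pfm.tsv")
        _write_pfm(pfm, pfm_path)
        outputs["pfm.tsv"] = pfm_path
        report["profiles"] = {
            "tss_total": tss.total(),
            "donor_total": donors.total(),
            "donor_band_mass": donors.mass_in(band_lo, band_hi),
            "motif_total": motif.total(),
            "pfm_sequences": pfm.n_sequences,
        }

    filtered: list[ev.SpliceEvent] = []
    if "events" in config.stages:
        table = iio.read_event_table(config.events_tsv)
        filtered = ev.filter_significant(
            table, min_prob=config.min_prob, min_dpsi=config.min_dpsi
        )
        dist = ev.type_distribution(filtered)
        direction = ev.direction_analysis(filtered)
        ratio = ev.aa_ad_ratio(filtered)
        filt_path = os.path.join(config.out_dir, "filtered_events.tsv")
        iio.write_table(filtered, filt_path, columns=iio.EVENT_COLUMNS)
        outputs["filtered_events.tsv"] = filt_path
        summary_json = {
            "n_events_input": len(table),
            "n_events_significant": len(filtered),
            "type_distribution": {
                t: {"count": c, "pct": p} for t, (c, p) in dist.items()
            },
            "direction": {
                "per_type": direction.per_type,
                "table": direction.table,
                "odds_ratio": direction.odds_ratio,
                "p_value": direction.p_value,
                "degenerate": direction.degenerate,
            },
            "aa_ad_ratio": ratio,
        }
        ev_path = os.path.join(config.out_dir, "events_summary.json")
        with open(ev_path, "w") as fh:
            json.dump(summary_json, fh, indent=1, sort_keys=True)
            fh.write("\n")
        outputs["events_summary.json"] = ev_path
        report["events"] = summary_json

    if "overlap" in config.stages:
        if config.gene_list_a and config.gene_list_b and config.universe_list:
            set_a = iio.read_gene_list(config.gene_list_a)
            set_b = iio.read_gene_list(config.gene_list_b)
            universe = iio.read_gene_list(config.universe_list)
        elif summary is not None and filtered and models:
            set_a = set(summary["gene_id"])
            set_b = {e.gene_id for e in filtered}
            universe = {g.gene_id for g in models}
            log.info("overlap universe defaulting to all %d annotated genes",
                     len(universe))
        else:
            set_a = set_b = universe = set()
        if universe:
            result = ss.fisher_overlap(set_a, set_b, universe)
            venn = ss.venn_counts([set_a, set_b])
            overlap_json = {
                "table": [result.a, result.b, result.c, result.d],
                "odds_ratio": result.odds_ratio,
                "p_value": result.p_value,
                "universe_size": result.universe_size,
                "venn": venn,
            }
            ov_path = os.path.join(config.out_dir, "overlap.json")
            with open(ov_path, "w") as fh:
                json.dump(overlap_json, fh, indent=1, sort_keys=True)
                fh.write("\n")
            outputs["overlap.json"] = ov_path
            report["overlap"] = overlap_json

    manifest = {
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in params.items()},
        "seed": config.seed,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        "report": report,
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def _sites_in_donor_band(sites, models, min_exon_len, band):
    """Sites whose peak falls within ``band`` of a qualifying donor."""
    out = []
    trees = st._gene_trees(models)
    from intervaltree import IntervalTree

    for s in sites:
        hits = trees.get((s.chrom, s.strand), IntervalTree())[s.start : s.end]
        keep = False
        for hit in hits:
            g = models[hit.data]
            for donor, exon_len in zip(g.donors, g.donor_upstream_exon_lengths()):
                if exon_len < min_exon_len:
                    continue
                off = s.peak - donor if g.strand == "+" else donor - s.peak
                if band[0] <= off <= band[1]:
                    keep = True
        if keep:
            out.append(s)
    return out
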