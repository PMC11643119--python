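# Methods

This note documents the models and procedures `iclipkit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Coordinates and formats

All internal coordinates are 0-based, half-open, on the forward strand;
strand affects only sequence orientation and strand-oriented offsets. BED
is read natively; GFF3 (1-based inclusive) is converted on read, so a GFF3
record `start..end` becomes `[start−1, end)`. Readers reject malformed
records with the offending line number rather than repairing them; this is
deliberate — every silent repair is an invisible analysis decision.

One representative transcript per gene is used everywhere, to avoid
ambiguous feature assignment. When no explicit mapping is supplied, the
transcript whose ID ends in `.1` is preferred (the convention of TAIR
representative models), else the transcript with the longest CDS, ties
broken lexicographically.

Binding sites round-trip through BED6 exactly when unclipped; a site
clipped at a chromosome edge stores its true peak in memory, but on
re-reading from BED the peak is recomputed as the interval midpoint, which
may differ for clipped records. Consumers that need 9-nt sequence windows
skip clipped sites.

## Binding-site definition

1. **PCR deduplication.** Reads sharing (chrom, strand, mapping start,
   random barcode) are collapsed to the first occurrence. Strand is part
   of the key: two libraries' reads mapping to opposite strands at one
   position are distinct molecules.
2. **Peak collapsing.** Maximal runs of crosslink peaks at consecutive
   positions on one chrom/strand are replaced by the member with the
   highest peak-caller score. Score ties keep the 5′-most peak — a
   deterministic, orientation-consistent rule. Two peaks at the identical
   position are an input error (a peak caller emits one record per
   position).
3. **Extension.** Each peak is extended ±4 nt (`ext`, default 4) into a
   site of width 2·ext+1 = 9 nt whose centre is the binding-site peak.
   Sites running off a chromosome end are clipped and flagged, not
   dropped: counts stay faithful while sequence-based consumers can skip
   them.
4. **Control subtraction.** A signal site is removed when some control
   site on the same chrom/strand has peak-to-peak distance ≤ `window`
   (default 9 nt). Peak distance was chosen over interval gap or overlap
   because it is symmetric and matches the single-nucleotide resolution
   of the peak calls; one control site may remove several signal sites.
5. **Feature assignment.** A site is assigned to every feature type
   (5′UTR, CDS, intron, 3′UTR) of a same-strand gene that its 9-nt
   interval overlaps by ≥ 1 nt; antisense overlap does not count, and
   sites overlapping no gene are intergenic. Sites overlapping only a
   non-coding gene are recorded against its exon/intron structure. The
   per-gene category percentages are reported over protein-coding genes
   with ≥ 1 site; a gene can appear in several categories, so the
   percentages may sum to more than 100.

## k-mer enrichment

Hexamer counts (`k` = 6, matching the length scale of short RBP motifs)
over all overlapping windows of the 9-nt site sequences; windows
containing N are skipped. Enrichment per k-mer is

z = (observed − mean of resampled counts) / sd of resampled counts,

with the null built by 1000 iterations; each iteration draws, for every
width-9 site, one 9-nt window uniformly at random from the **mature
(spliced) transcript of that site's own target transcript**. This
per-transcript matching controls local sequence composition — the point
of the normalization. Choices within this scheme:

- **Per-site vs pooled sampling.** Default is one window per real site
  from that site's transcript; a `pooled` flag instead draws each window
  uniformly over all windows of all target transcripts. Per-site matching
  is the default because it preserves the per-transcript weighting of the
  observed counts.
- **Mature vs genomic sequence.** Sampling uses spliced transcript
  sequence, since targets are defined at transcript level; passing
  pre-mRNA sequences as the transcript dictionary gives the genomic mode.
- **Population sd** (divide by n) rather than sample sd; at 1000
  iterations the difference is ~0.05%, but the choice is pinned and
  tested so results are reproducible to the last digit.
- **Determinism and order invariance.** One root seed spawns independent
  per-iteration streams; sites are canonically sorted by coordinate
  before streams are consumed, so the result does not depend on input
  order.
- **Degenerate sd.** If the null sd of a k-mer is 0 and the observed
  count equals the null mean, z = 0; if it differs, z is undefined and
  the k-mer sorts after all defined z values.

Calibration: when the "observed" sites are themselves one draw of the
sampling scheme (no planted motif), the z-scores across hexamers behave
like standard-normal deviates — mean within ±0.1, sd within [0.8, 1.25]
at 1000 iterations. This is asserted in the test suite with fixed seeds.

## Positional metaprofiles

All offsets are strand-oriented: positive = downstream (3′) of the anchor.

- **TSS:** anchor is each gene's most-5′ transcript start; offsets are
  tallied over [0, 250] nt downstream. Sites not overlapping a gene are
  ignored.
- **5′ splice sites:** anchor is the first intronic base (offset 0);
  exonic positions are negative. Only donors whose upstream exon is
  ≥ 50 nt enter the profile, so short-exon genes do not dominate the
  near-donor window. The tally window defaults to [−50, +10]; the band
  used to select peaks for the sequence matrix defaults to [−35, −20],
  the region where upstream-of-donor binding concentrates. The window and
  band are exposed as parameters because "n nt upstream" conventions vary
  by a few nucleotides between text, methods and figures in the
  literature.
- **Motif anchors:** the genome is scanned strand-specifically for exact
  motif matches (default CAGA); each site peak is tallied at its offset
  to the *nearest* occurrence, offset 0 meaning the peak sits on the
  motif's first base. Equidistant ties count toward the upstream
  occurrence. An `all_occurrences` flag tallies every in-window match
  instead.
- **Position-frequency matrix:** fixed-width (default 21 nt, odd)
  strand-oriented windows centred on peaks are stacked directly into
  per-position base counts; since all windows have identical length, a
  multiple alignment before stacking would be an identity operation and
  is deliberately omitted. N bases are tallied separately per column so
  column sums remain auditable.

## Differential splicing

Events carry PSI of the inclusion form per condition; ΔPSI = PSI_test −
PSI_control is recomputed on read and must match the stored column within
1e-6. The significance filter keeps events with probability ≥ 0.9 and
|ΔPSI| ≥ 0.1, additionally requiring both alternative junctions observed
for AA/AD events and, for RI, at least one read in every control sample
or every test sample. The filter is monotone in both thresholds.

Direction analysis counts up (ΔPSI > 0) vs down (ΔPSI < 0) per type,
excluding exact zeros, and contrasts RI vs EI with a two-sided Fisher's
exact test; the odds ratio is (RI_up·EI_down)/(RI_down·EI_up). Fisher was
chosen for exactness on small 2×2 tables and for consistency with the
overlap testing elsewhere in the package. A zero margin makes the
contrast degenerate: p is reported as 1.0 with a warning flag. Under the
inclusion-form sign convention, "retention promoted" for RI means
ΔPSI > 0 and "exitron splicing enhanced" means ΔPSI < 0 for the
retained form.

Exitron junctions are splice junctions lying strictly inside a single
annotated CDS interval of a same-strand gene's representative transcript,
with ≥ 1 nt of CDS on both sides and length ≥ 9 nt (the minimum is a
conservative floor, exposed as a parameter, since intron-definition
minima differ between tools); frame is in-frame iff length mod 3 = 0 —
frame depends only on length, so shifting a junction by 3 nt never
changes its classification.

## Gene-set overlap

Fisher's exact test on the 2×2 table (both, A-only, B-only, neither)
within an **explicit, required universe**: the "neither" cell drives the
p-value, and a silently assumed universe would fabricate unverifiable
significance. The two-sided p is the sum of hypergeometric probabilities
of all tables with the same margins whose probability does not exceed the
observed one (with a 1e-7 relative epsilon when ranking equal-probability
tables — the standard convention). The p-value is computed by vectorized
hypergeometric pmf summation; the test suite verifies it against
`scipy.stats.fisher_exact` on random tables and against exact-integer
enumeration for every table with universe ≤ 60. The odds ratio is
(a·d)/(b·c), undefined when b·c = 0. A Benjamini–Hochberg helper is
provided but never applied implicitly.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the realism of a genome:

- **Genome/annotation:** non-overlapping genes on both strands of 2
  chromosomes; ~80% protein-coding (5′UTR, 2–5 CDS exons of 90–240 nt,
  introns 80–200 nt, 3′UTR), ~20% non-coding two-exon genes; i.i.d.
  uniform-ACGT background, chosen so the k-mer null is analytically
  transparent.
- **Crosslink peaks:** a mixture over peak classes — motif-planted (20%:
  the genome is mutated so the peak sits on a planted CAGA first base),
  TSS-proximal (35%, exponential offsets with scale 60 nt truncated at
  250), donor-band (25%, uniform in [−30, −25] nt upstream of 5′ splice
  sites), and uniform-exonic (remainder); 30% of non-motif peaks get a
  CU-rich 9-nt window written around them. Later sequence plants never
  overwrite earlier ones. Control peaks are uniform over exonic positions
  at 8% of the signal count (roughly the ratio of control to signal sites
  in a GFP-background iCLIP comparison). Reads per peak are
  1 + Poisson(2) with distinct random barcodes, duplicated with
  probability 0.3.
- **Event tables:** per-type planted counts (defaults RI 200, EI 200,
  CE 60, AA 42, AD 30 — an AA/AD ratio of 1.4) with |ΔPSI| uniform in
  [0.1, 0.45], probability uniform in [0.9, 1], and per-type direction
  biases (RI 76.2% up, EI 29.8% up, others balanced); null events are
  constructed to fail exactly one filter clause each (low probability,
  small |ΔPSI|, missing AA/AD junction, or zero RI read support in both
  conditions).
- Ground truth (peak classes, duplicate counts, planted event indices and
  directions) is emitted as sidecar JSON, never encoded in record names,
  so parsers cannot cheat.

What passing tests show: the pipeline's rules are implemented exactly
(oracle equivalence), the enrichment null is calibrated, and planted
positional/motif/direction structure at realistic effect sizes is
recovered. What they do not show: behaviour under mapping artefacts,
crosslinking sequence bias (UV crosslinking favours uridines), non-uniform
genomic composition, overlapping gene models, or transcript-abundance
weighting — real libraries have all of these, and conclusions about a real
protein still require the usual orthogonal validation.

One interaction worth knowing: when strong CU-rich planting and CAGA
planting are both active, individual CU-rich hexamers can outrank
CAGA-containing ones in z (CU k-mers are the most frequent, CAGA k-mers
the most concentrated) — consistent with polypyrimidine motifs appearing
among the most frequent but less enriched hexamers in real data. The
motif-recovery test therefore plants the motif alone; the default
simulated study keeps both signals.

## Problem sizes and reproducibility

Defaults run a 300-gene, ~1000-peak, ~680-event study (about three
binding sites per target gene, the ratio of a small iCLIP study); the acceptance
script uses exactly these defaults with 1000 resampling iterations and
completes in seconds. Every stage is deterministic given its seed: one
root seed spawns per-component streams (genome, crosslinks, events,
resampling iterations), and `run_all` writes a manifest with the resolved
parameter set and SHA-256 checksums of all outputs, so a rerun can be
verified byte-exact.
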