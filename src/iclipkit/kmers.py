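"""k-mer counting and enrichment with a transcript-matched resampling null.

The enrichment statistic is a z-score per k-mer: observed count in the
binding-site sequences minus the mean count over resampled sequence sets,
divided by the standard deviation over those sets. Each resampled set draws,
for every real binding site, one same-width window uniformly at random from
the mature sequence of that site's own transcript, so the null is matched to
the local sequence composition of the bound transcripts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .sites import BindingSite

SITE_WIDTH = 9
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class KmerEnrichmentResult:
    """Observed count, resampling-null mean/sd, and z-score for one k-mer.

    ``z`` is None when the null sd is zero and the observed count differs
    from the null mean (the statistic is undefined there); it is 0.0 when
    sd is zero but observed equals the mean.
    """

    kmer: str
    observed: int
    null_mean: float
    null_sd: float
    z: float | None


def count_kmers(sequences: list[str], k: int = 6) -> dict[str, int]:
    """Count every overlapping k-length window across all sequences,
    skipping windows that contain N."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" not in window:
                counts[window] += 1
    return dict(counts)


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of the k-mer starting at each position; -1 where the
    window contains N."""
    codes = _encode(seq.upper())
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        out = out * 4 + np.where(col < 0, 0, col)
        bad |= col < 0
    out[bad] = -1
    return out


def _decode_kmer(code: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(letters))


def resampling_null(
    sites: list[BindingSite],
    site_transcripts: list[str],
    transcripts: dict[str, str],
    n_iter: int = 1000,
    k: int = 6,
    seed: int = 0,
    pooled: bool = False,
) -> dict[str, tuple[float, float]]:
    """Per-k-mer (mean, sd) of counts over ``n_iter`` resampled site sets.

    Each iteration draws one ``SITE_WIDTH``-nt window uniformly at random
    from the mature transcript of every usable (width-9) site, counts
    k-mers across the drawn windows, and the per-k-mer mean and population
    sd over iterations are returned. Deterministic given ``seed`` and
    invariant to the input order of sites (sites are canonically sorted
    before streams are assigned).

    With ``pooled=True`` each draw instead picks a window uniformly over
    all windows of all targeted transcripts (composition matched to the
    pooled target set rather than per site). To sample from unspliced
    sequence, pass pre-mRNA sequences as ``transcripts``.

    Raises if a usable site maps to a transcript shorter than the site
    width.
    """
    if len(sites) != len(site_transcripts):
        raise ValueError("sites and site_transcripts must be parallel")
    usable = [
        (s, tx)
        for s, tx in zip(sites, site_transcripts)
        if len(s) == SITE_WIDTH
    ]
    # canonical order makes the result independent of input ordering
    usable.sort(key=lambda p: (p[0].chrom, p[0].strand, p[0].start, p[0].end))

    # group sites by transcript, keeping canonical group order
    group_order: list[str] = []
    group_count: Counter[str] = Counter()
    for s, tx in usable:
        if tx not in transcripts:
            raise KeyError(f"unknown transcript {tx!r}")
        if len(transcripts[tx]) < SITE_WIDTH:
            raise ValueError(
                f"site {s.chrom}{s.strand}:{s.start}-{s.end} maps to "
                f"transcript {tx} shorter than {SITE_WIDTH} nt"
            )
        if tx not in group_count:
            group_order.append(tx)
        group_count[tx] += 1

    n_kmers = 4 ** k
    win_kmers = SITE_WIDTH - k + 1
    if win_kmers <= 0:
        return {}

    # Each group is (n_draws, concatenated kmer-code array, array of code
    # offsets of the valid window starts). Per-site mode has one group per
    # transcript; pooled mode has a single group spanning all transcripts.
    groups: list[tuple[int, np.ndarray, np.ndarray]] = []
    if pooled and usable:
        code_parts, start_parts, offset = [], [], 0
        for tx in group_order:
            codes = _kmer_codes(transcripts[tx], k)
            n_starts = len(transcripts[tx]) - SITE_WIDTH + 1
            code_parts.append(codes)
            start_parts.append(np.arange(n_starts) + offset)
            offset += len(codes)
        groups.append(
            (len(usable), np.concatenate(code_parts), np.concatenate(start_parts))
        )
    else:
        for tx in group_order:
            codes = _kmer_codes(transcripts[tx], k)
            n_starts = len(transcripts[tx]) - SITE_WIDTH + 1
            groups.append((group_count[tx], codes, np.arange(n_starts)))

    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n_iter)]
    counts = np.zeros((n_iter, n_kmers), dtype=np.int64)
    offs = np.arange(win_kmers)
    for it, rng in enumerate(rngs):
        drawn = []
        for m, codes, window_offsets in groups:
            picks = window_offsets[rng.integers(0, len(window_offsets), size=m)]
            drawn.append(codes[picks[:, None] + offs[None, :]].ravel())
        if drawn:
            allcodes = np.concatenate(drawn)
            allcodes = allcodes[allcodes >= 0]
            counts[it] = np.bincount(allcodes, minlength=n_kmers)

    mean = counts.mean(axis=0)
    sd = counts.std(axis=0)  # population sd
    nonzero = np.flatnonzero(counts.any(axis=0))
    return {
        _decode_kmer(int(c), k): (float(mean[c]), float(sd[c])) for c in nonzero
    }


def kmer_zscores(
    observed: dict[str, int],
    null: dict[str, tuple[float, float]],
) -> list[KmerEnrichmentResult]:
    """z = (observed - null mean) / null sd per k-mer, sorted by z
    descending; k-mers with undefined z sort last."""
    results = []
    for kmer in sorted(set(observed) | set(null)):
        obs = observed.get(kmer, 0)
        mean, sd = null.get(kmer, (0.0, 0.0))
        if sd > 0:
            z: float | None = (obs - mean) / sd
        elif obs == mean:
            z = 0.0
        else:
            z = None
        results.append(
            KmerEnrichmentResult(
                kmer=kmer, observed=obs, null_mean=mean, null_sd=sd, z=z
            )
        )
    results.sort(
        key=lambda r: (r.z is None, -(r.z if r.z is not None else 0.0), r.kmer)
    )
    return results
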