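"""Differential alternative-splicing event filtering and summaries.

Events follow the delta-style table of splice-graph quantifiers: one row per
event with a type (AA alternative acceptor, AD alternative donor, CE
cassette exon, RI retained intron, EI exitron), percent-spliced-in (PSI) of
the inclusion form per condition, their difference dPSI, a posterior
probability that the event changed, and per-sample read support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .core import GeneModel, Interval

EVENT_TYPES = ("AA", "AD", "CE", "RI", "EI")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event between two conditions.

    ``psi_a``/``psi_b`` are the PSI of the inclusion form in the control and
    test condition; ``delta_psi`` must equal psi_b - psi_a within 1e-6.
    ``junctions_detected`` records whether each of the two alternative
    junctions of an AA/AD event was observed in the data.
    """

    gene_id: str
    iv: Interval
    etype: str
    psi_a: float
    psi_b: float
    delta_psi: float
    probability: float
    junctions_detected: tuple[bool, bool] = (True, True)
    reads_control: tuple[int, ...] = ()
    reads_test: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        for name in ("psi_a", "psi_b", "probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.delta_psi - (self.psi_b - self.psi_a)) > 1e-6:
            raise ValueError(
                f"delta_psi {self.delta_psi} does not match "
                f"psi_b - psi_a = {self.psi_b - self.psi_a}"
            )
        if any(r < 0 for r in self.reads_control + self.reads_test):
            raise ValueError("negative read support")


@dataclass
class DirectionSummary:
    """Up/down counts per event type and the RI-vs-EI direction contrast."""

    per_type: dict[str, dict]  # type -> {n_up, n_down, pct_up}
    table: tuple[tuple[int, int], tuple[int, int]]  # (RI, EI) x (up, down)
    odds_ratio: float | None
    p_value: float
    degenerate: bool = False  # a contrast margin was zero


def detect_exitrons(
    junctions: list[Interval],
    models: list[GeneModel],
    min_len: int = 9,
) -> list[tuple[Interval, str, str]]:
    """Identify exitron junctions: splice junctions lying strictly inside a
    single annotated CDS interval of a same-strand gene's representative
    transcript (>=1 nt margin at both ends) with length >= ``min_len``.

    Returns (junction, gene_id, frame) with frame = "in_frame" iff the
    removed length is divisible by 3.
    """
    out = []
    for j in junctions:
        if len(j) < min_len:
            continue
        for g in models:
            if g.chrom != j.chrom or g.strand != j.strand:
                continue
            for cds in g.cds():
                if cds.start < j.start and j.end < cds.end:
                    frame = "in_frame" if len(j) % 3 == 0 else "out_of_frame"
                    out.append((j, g.gene_id, frame))
                    break
            else:
                continue
            break
    return out


def filter_significant(
    events: list[SpliceEvent],
    min_prob: float = 0.9,
    min_dpsi: float = 0.1,
) -> list[SpliceEvent]:
    """Keep events with probability >= min_prob and |dPSI| >= min_dpsi,
    requiring both alternative junctions for AA/AD events and, for RI
    events, at least one read in every control sample or every test
    sample."""
    out = []
    for e in events:
        if e.probability < min_prob or abs(e.delta_psi) < min_dpsi:
            continue
        if e.etype in ("AA", "AD") and not all(e.junctions_detected):
            continue
        if e.etype == "RI":
            ctrl_ok = bool(e.reads_control) and min(e.reads_control) >= 1
            test_ok = bool(e.reads_test) and min(e.reads_test) >= 1
            if not (ctrl_ok or test_ok):
                continue
        out.append(e)
    return out


def type_distribution(
    events: list[SpliceEvent],
) -> dict[str, tuple[int, float]]:
    """Counts and percentages per event type over the given events."""
    if not events:
        return {}
    counts = Counter(e.etype for e in events)
    total = len(events)
    return {
        t: (counts[t], 100.0 * counts[t] / total)
        for t in EVENT_TYPES
        if counts[t]
    }


def direction_analysis(events: list[SpliceEvent]) -> DirectionSummary:
    """Per-type up/down split by the sign of dPSI (zeros excluded) and the
    RI-vs-EI direction contrast tested with a two-sided Fisher's exact
    test. Odds ratio is (RI_up * EI_down) / (RI_down * EI_up)."""
    per_type: dict[str, dict] = {}
    for t in EVENT_TYPES:
        ups = sum(1 for e in events if e.etype == t and e.delta_psi > 0)
        downs = sum(1 for e in events if e.etype == t and e.delta_psi < 0)
        if ups + downs:
            per_type[t] = {
                "n_up": ups,
                "n_down": downs,
                "pct_up": 100.0 * ups / (ups + downs),
            }

    ri = per_type.get("RI", {"n_up": 0, "n_down": 0})
    ei = per_type.get("EI", {"n_up": 0, "n_down": 0})
    table = ((ri["n_up"], ri["n_down"]), (ei["n_up"], ei["n_down"]))
    margins = (
        table[0][0] + table[0][1],
        table[1][0] + table[1][1],
        table[0][0] + table[1][0],
        table[0][1] + table[1][1],
    )
    degenerate = 0 in margins
    if degenerate:
        p_value = 1.0
    else:
        _, p_value = stats.fisher_exact(table, alternative="two-sided")
    denom = table[0][1] * table[1][0]
    numer = table[0][0] * table[1][1]
    odds_ratio = numer / denom if denom else None
    return DirectionSummary(
        per_type=per_type,
        table=table,
        odds_ratio=odds_ratio,
        p_value=float(p_value),
        degenerate=degenerate,
    )


def aa_ad_ratio(events: list[SpliceEvent]) -> float | None:
    """count(AA) / count(AD); None when no AD events are present."""
    n_aa = sum(1 for e in events if e.etype == "AA")
    n_ad = sum(1 for e in events if e.etype == "AD")
    if n_ad == 0:
        return None
    return n_aa / n_ad
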