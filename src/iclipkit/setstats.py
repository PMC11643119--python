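"""Gene-set overlap statistics: Fisher's exact test and Venn counting.

The universe for an overlap test is a required explicit input: p-values on
2x2 tables depend on the "neither" cell, and a silently assumed universe
would fabricate unverifiable significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class OverlapResult:
    """2x2 overlap table (both, A-only, B-only, neither) with Fisher
    statistics."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float | None
    p_value: float
    universe_size: int


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]]:
    the sum of hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed one."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    # relative epsilon absorbs float noise when ranking equal-probability
    # tables, matching the standard two-sided convention
    p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    return float(min(1.0, p))


def fisher_two_sided_curve(r1: int, c1: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-values for every table with margins (r1, c1, n).

    Returns (support, p) where support lists the feasible values of the
    overlap cell a. Vectorized over the whole support at once."""
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    thresh = pmf[:, None] * (1 + 1e-7)
    p = np.minimum(1.0, np.where(pmf[None, :] <= thresh, pmf[None, :], 0.0).sum(axis=1))
    return support, p


def fisher_overlap(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
) -> OverlapResult:
    """Fisher's exact test for the overlap of two gene sets within an
    explicit universe. Odds ratio is (a*d)/(b*c), None when b*c == 0."""
    extra_a = set_a - universe
    extra_b = set_b - universe
    if extra_a or extra_b:
        raise ValueError(
            "sets not contained in universe; offending IDs: "
            f"{sorted(extra_a | extra_b)[:20]}"
        )
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    p = fisher_two_sided(a, b, c, d)
    odds = (a * d) / (b * c) if b * c else None
    return OverlapResult(
        a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p,
        universe_size=len(universe),
    )


def overlap_fraction(set_a: set[str], set_b: set[str]) -> float:
    """|A intersect B| / |A|."""
    if not set_a:
        return float("nan")
    return len(set_a & set_b) / len(set_a)


def venn_counts(sets: list[set[str]]) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 sets.

    Region keys name the member sets: for two sets A, B the keys are
    "A", "B", "AB"; for three, additionally "C", "AC", "BC", "ABC"."""
    if len(sets) == 2:
        a, b = sets
        return {
            "A": len(a - b),
            "B": len(b - a),
            "AB": len(a & b),
        }
    if len(sets) == 3:
        a, b, c = sets
        return {
            "A": len(a - b - c),
            "B": len(b - a - c),
            "C": len(c - a - b),
            "AB": len((a & b) - c),
            "AC": len((a & c) - b),
            "BC": len((b & c) - a),
            "ABC": len(a & b & c),
        }
    raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(sets)}")


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (helper; never applied
    implicitly by the overlap test)."""
    return list(stats.false_discovery_control(np.asarray(p_values), method="bh"))
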