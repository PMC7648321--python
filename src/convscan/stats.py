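"""Classical tests for the ACG overlap and count analyses.

Thin, explicit wrappers over scipy: two-sided Fisher's exact test
(minimum-likelihood tail rule), chi-square goodness of fit against an equal
split, chi-square critical values, Benjamini-Hochberg step-up adjustment
(on probability or percent scales), and union-based 2x2 overlap tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class OverlapTable:
    """2x2 overlap table: [[a, b], [c, d]].

    a / b: overlapping vs non-overlapping ACGs over the union of two ACG
    sets; c / d: the same for the neutrally sequence-convergent gene sets.
    """

    a: int
    b: int
    c: int
    d: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    test: str
    p: float
    statistic: float | None = None
    df: int | None = None


def build_overlap_table(acg_a, acg_b, neutral_a, neutral_b) -> OverlapTable:
    """Union-based overlap table from two ACG and two neutral gene-id sets.

    Each row counts genes once over the union of its two sets:
    (overlap, union - overlap).
    """
    acg_a, acg_b = set(acg_a), set(acg_b)
    neutral_a, neutral_b = set(neutral_a), set(neutral_b)
    # disjointness holds per hypothesis; a gene may be an ACG under one
    # hypothesis and neutrally sequence-convergent under the other
    clash = (acg_a & neutral_a) | (acg_b & neutral_b)
    if clash:
        raise ValueError(
            f"genes in both ACG and neutral inputs: {sorted(clash)[:5]}"
        )
    a = len(acg_a & acg_b)
    c = len(neutral_a & neutral_b)
    return OverlapTable(
        a, len(acg_a | acg_b) - a, c, len(neutral_a | neutral_b) - c
    )


def fisher_two_sided(table: OverlapTable) -> TestResult:
    """Two-tailed Fisher's exact test, minimum-likelihood tail summation."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in overlap table; p = 1")
        return TestResult("fisher_two_sided", 1.0)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher_two_sided", float(min(p, 1.0)))


def chisq_gof(counts) -> TestResult:
    """Chi-square goodness of fit against an equal split, no correction."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 categories")
    if counts.sum() <= 0:
        raise ValueError("zero total count")
    stat, p = sps.chisquare(counts)
    return TestResult(
        "chisq_gof", float(p), statistic=float(stat), df=counts.size - 1
    )


def chisq_critical(df: int, alpha: float = 0.05) -> float:
    """(1 - alpha) quantile of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.ppf(1.0 - alpha, df))


def bh_adjust(values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Accepts either probabilities in [0, 1] or percentile ranks in [0, 100];
    the scale of the input is preserved in the output.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        return []
    if vals.min() < 0 or vals.max() > 100:
        raise ValueError("values must lie in [0, 1] or [0, 100]")
    scale = 100.0 if vals.max() > 1 else 1.0
    p = vals / scale
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return list(adj * scale)
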