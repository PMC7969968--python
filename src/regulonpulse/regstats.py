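"""Regulator-activity comparison between populations.

The central statistic is the two-sided Fisher exact test on a 2x2 table of
per-regulator mapped-gene counts in two populations. The two-sided p-value
is the sum of hypergeometric probabilities, over all tables with the
observed margins, that do not exceed the observed table's probability
(with the customary 1 + 1e-7 relative tie tolerance); the enumeration is
done in log space for stability. Regulators with raw p < 0.05 are flagged
``selected``; Benjamini-Hochberg adjusted p-values across all tested
regulators are always reported alongside.

Also here: exact Venn-style overlap counts of differential gene sets
across any number of populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .diffexpr import DEGSet, bh_adjust
from .errors import UsageError
from .trnmap import RegulatorActivity

TIE_TOLERANCE = 1e-7


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 contingency table.

    Returns ``(odds_ratio, pvalue)``. The odds ratio is ``(a*d)/(b*c)``:
    ``inf`` when only ``b*c`` is zero and NaN when both products vanish
    (undefined). Degenerate tables (an empty row or column) have p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise UsageError("table must be 2x2")
    if (t < 0).any() or (t != np.round(t)).any():
        raise UsageError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in t.ravel())
    if a * d == 0 and b * c == 0:
        odds = math.nan
    elif b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)

    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return odds, 1.0
    # support of the hypergeometric count in cell a given the margins
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, n, c1, r1)
    log_obs = logp[a - lo] + math.log1p(TIE_TOLERANCE)
    pvalue = float(np.exp(logsumexp(logp[logp <= log_obs])))
    return odds, min(pvalue, 1.0)


@dataclass
class FisherComparison:
    """One regulator's 2x2 comparison between two populations."""

    regulator: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float
    padj: float
    selected: bool
    populations: tuple[str, str]


def compare_regulators(
    activity_a: RegulatorActivity,
    activity_b: RegulatorActivity,
    *,
    table_mode: str = "regulon",
    direction: str = "both",
    select_alpha: float = 0.05,
) -> list[FisherComparison]:
    """Fisher-compare per-regulator mapped counts between two populations.

    ``table_mode="regulon"`` (default) conditions on regulon size: rows are
    the two populations, columns are (regulon genes mapped, regulon genes
    not mapped). ``table_mode="mapped"`` instead takes columns (genes
    mapped to this regulator, genes mapped to any other regulator).
    ``direction`` pools up+down counts ("both", matching a comparison of
    genes that changed expression in any direction) or restricts to one
    ("up" / "down").

    Selection mirrors the raw p < ``select_alpha`` convention; BH-adjusted
    p-values across all compared regulators are reported as well.
    """
    if table_mode not in ("regulon", "mapped"):
        raise UsageError(f"unknown table_mode {table_mode!r}")
    if direction not in ("both", "up", "down"):
        raise UsageError(f"unknown direction {direction!r}")
    ta, tb = activity_a.table, activity_b.table
    if list(ta.index) != list(tb.index):
        raise UsageError("activities compare different regulator sets")
    if not ta["regulon_size"].equals(tb["regulon_size"]):
        raise UsageError(
            "regulon sizes differ between activities; both must come from one network"
        )

    def counts(t: pd.DataFrame) -> pd.Series:
        if direction == "both":
            return t["mapped_count"]
        return t[f"{direction}_count"]

    ca, cb = counts(ta), counts(tb)
    rows: list[FisherComparison] = []
    pvals: list[float] = []
    for reg in ta.index:
        a, c = int(ca[reg]), int(cb[reg])
        if table_mode == "regulon":
            size = int(ta.loc[reg, "regulon_size"])
            b, d = size - a, size - c
        else:
            b, d = int(ca.sum()) - a, int(cb.sum()) - c
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        pvals.append(p)
        rows.append(
            FisherComparison(
                regulator=str(reg),
                table=((a, b), (c, d)),
                odds_ratio=odds,
                pvalue=p,
                padj=math.nan,
                selected=p < select_alpha,
                populations=(activity_a.contrast, activity_b.contrast),
            )
        )
    padj = bh_adjust(pvals)
    for i, row in enumerate(rows):
        rows[i] = FisherComparison(
            row.regulator,
            row.table,
            row.odds_ratio,
            row.pvalue,
            float(padj[i]),
            row.selected,
            row.populations,
        )
    return rows


def comparisons_frame(comparisons: Iterable[FisherComparison]) -> pd.DataFrame:
    """Flatten comparisons into the TSV-ready long table."""
    rows = [
        {
            "regulator": c.regulator,
            "a": c.table[0][0],
            "b": c.table[0][1],
            "c": c.table[1][0],
            "d": c.table[1][1],
            "odds_ratio": c.odds_ratio,
            "pvalue": c.pvalue,
            "padj": c.padj,
            "selected": c.selected,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=["regulator", "a", "b", "c", "d", "odds_ratio", "pvalue", "padj", "selected"],
    )


def overlap_counts(
    degsets: Mapping[str, DEGSet],
) -> dict[str, dict[tuple[str, ...], int]]:
    """Exact Venn region counts per direction across populations.

    For each direction, every non-empty population combination maps to the
    number of genes belonging to exactly those populations' sets (the
    exclusive region of a Venn diagram); the 2^k - 1 region counts sum to
    the union size.
    """
    if len(degsets) < 2:
        raise UsageError("need at least two populations to overlap")
    labels = list(degsets)
    out: dict[str, dict[tuple[str, ...], int]] = {}
    for direction in ("up", "down"):
        sets = {lab: getattr(degsets[lab], direction) for lab in labels}
        regions: dict[tuple[str, ...], int] = {}
        for k in range(1, len(labels) + 1):
            for combo in combinations(labels, k):
                inside = frozenset.intersection(*(sets[lab] for lab in combo))
                outside = frozenset().union(
                    *(sets[lab] for lab in labels if lab not in combo)
                )
                regions[combo] = len(inside - outside)
        out[direction] = regions
    return out
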