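"""DESeq-style two-group differential expression.

The test follows the classic negative-binomial count workflow: per-sample
size factors by the median-of-ratios method, a Wald test on the log2 fold
change of normalized group means, and Benjamini-Hochberg adjustment across
genes. Dispersion is estimated per gene by the method of moments and, by
default, moderated through a robust parametric mean-dispersion trend
``alpha(mu) = a0 + a1 / mu`` fitted across all genes — with two or three
replicates a raw per-gene dispersion has so few degrees of freedom that the
Wald p-values are badly anti-conservative, and information sharing across
genes is what makes the calibration/sensitivity trade-off work (the same
reason DESeq fits a mean-variance trend). ``dispersion_mode`` selects
"trend" (default), "gene" (raw per-gene moments) or "max" (elementwise
maximum of the two, the conservative choice).

Significance calls use the conventional thresholds for this kind of study:
adjusted p < 0.1 and fold change strictly greater than twofold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, UsageError
from .formats import CountMatrix

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5  # added to normalized group means for log2fc stability


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def size_factors(matrix: CountMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For each gene with nonzero counts in *all* samples, form the ratio of
    its count to its geometric mean across samples; a sample's factor is
    the median of those ratios.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise UsageError("counts must be a non-empty gene x sample matrix")
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ComputationError(
            "no gene has nonzero counts in every sample; filter the matrix first"
        )
    sub = arr[all_nonzero]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    return np.median(sub / geo_mean[:, None], axis=0)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-gene differential-expression table for one contrast.

    ``table`` is indexed by gene id with columns ``base_mean`` (mean
    normalized count over both groups), ``log2fc`` (B over A), ``pvalue``
    and ``padj``; the p columns are NaN for genes with all-zero counts.
    """

    condition_b: str
    condition_a: str
    table: pd.DataFrame

    @property
    def contrast(self) -> str:
        return f"{self.condition_b}:{self.condition_a}"

    def summary(self, alpha: float = 0.1, fold_cutoff: float = 2.0) -> str:
        t = self.table
        tested = int(t["pvalue"].notna().sum())
        lfc = np.log2(fold_cutoff)
        up = int(((t["padj"] < alpha) & (t["log2fc"] > lfc)).sum())
        down = int(((t["padj"] < alpha) & (t["log2fc"] < -lfc)).sum())
        lines = [
            f"Differential expression: {self.condition_b} vs {self.condition_a}",
            f"  genes tested            {tested}",
            f"  up   (padj<{alpha:g}, >{fold_cutoff:g}x) {up}",
            f"  down (padj<{alpha:g}, >{fold_cutoff:g}x) {down}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# dispersion trend
# ---------------------------------------------------------------------------


def _fit_dispersion_trend(
    mu: np.ndarray, alpha_mom: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Robust least-squares fit of alpha(mu) = a0 + a1/mu.

    Genes with non-positive moment estimates are excluded; one trimming
    pass drops >3-sigma residuals so a planted minority of truly
    differential genes cannot drag the trend.
    """
    ok = (alpha_mom > 0) & (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        level = float(np.median(alpha_mom[ok])) if ok.any() else 0.01
        return lambda m: np.full(np.shape(m), max(level, DISPERSION_FLOOR))
    x = np.c_[np.ones(int(ok.sum())), 1.0 / mu[ok]]
    y = alpha_mom[ok]
    coef = np.zeros(2)
    for _ in range(2):
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        keep = np.abs(resid) < 3.0 * np.std(resid)
        if keep.all() or keep.sum() < 10:
            break
        x, y = x[keep], y[keep]
    a0, a1 = coef
    return lambda m: np.maximum(a0 + a1 / np.maximum(m, 1e-12), DISPERSION_FLOOR)


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------


def de_test(
    matrix: CountMatrix,
    condition_a: str,
    condition_b: str,
    *,
    dispersion_mode: str = "trend",
) -> DEResult:
    """Wald test of condition B against condition A.

    Counts are normalized by median-of-ratios size factors computed on the
    samples of the two groups. The statistic is
    ``log2((mean_B + 0.5)/(mean_A + 0.5))`` divided by its delta-method
    standard error under the NB variance ``m + alpha * m**2``; two-sided
    normal p-values, NaN for genes with all-zero counts in both groups.
    """
    if dispersion_mode not in ("trend", "gene", "max"):
        raise UsageError(f"unknown dispersion_mode {dispersion_mode!r}")
    samples_a = matrix.samples_for(condition_a)
    samples_b = matrix.samples_for(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise UsageError(
            f"both conditions need >= 2 replicates "
            f"({condition_a}: {len(samples_a)}, {condition_b}: {len(samples_b)})"
        )
    sub = matrix.counts[samples_a + samples_b]
    s = size_factors(np.asarray(sub, dtype=float))
    q = np.asarray(sub, dtype=float) / s
    n_a, n_b = len(samples_a), len(samples_b)
    qa, qb = q[:, :n_a], q[:, n_a:]
    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)

    # pooled within-group variance of normalized counts, n_a + n_b - 2 df
    ss = ((qa - mean_a[:, None]) ** 2).sum(axis=1) + (
        (qb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    v = ss / (n_a + n_b - 2)
    base_mean = (n_a * mean_a + n_b * mean_b) / (n_a + n_b)
    z_all = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (v - base_mean * z_all) / base_mean**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)

    if dispersion_mode == "gene":
        alpha = np.maximum(alpha_mom, DISPERSION_FLOOR)
    else:
        trend = _fit_dispersion_trend(base_mean, alpha_mom)(base_mean)
        if dispersion_mode == "trend":
            alpha = np.maximum(trend, DISPERSION_FLOOR)
        else:
            alpha = np.maximum(np.maximum(alpha_mom, trend), DISPERSION_FLOOR)

    z_a = float(np.mean(1.0 / s[:n_a]))
    z_b = float(np.mean(1.0 / s[n_a:]))
    var_mean_a = (mean_a * z_a + alpha * mean_a**2) / n_a
    var_mean_b = (mean_b * z_b + alpha * mean_b**2) / n_b
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mean_a / ((mean_a + PSEUDOCOUNT) ** 2 * ln2sq)
        + var_mean_b / ((mean_b + PSEUDOCOUNT) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    all_zero = np.asarray(sub).sum(axis=1) == 0
    pvalue = np.where(all_zero, np.nan, pvalue)

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=matrix.counts.index,
    )
    return DEResult(condition_b, condition_a, table)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing (NaN) entries are excluded from the number of tests and stay
    NaN in the output; order is restored. ``padj_(i) = min_{j>=i}
    p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise UsageError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    idx = np.where(finite)[0]
    m = len(idx)
    if m == 0:
        return out
    order = idx[np.argsort(p[idx], kind="stable")]
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# DEG sets
# ---------------------------------------------------------------------------


@dataclass
class DEGSet:
    """Thresholded signed gene sets for one contrast.

    ``up`` and ``down`` are disjoint; membership required *strictly*
    ``padj < alpha`` and ``|log2fc| > log2(fold_cutoff)``.
    """

    condition_b: str
    condition_a: str
    up: frozenset[str]
    down: frozenset[str]
    fold_cutoff: float
    alpha: float

    @property
    def contrast(self) -> str:
        return f"{self.condition_b}:{self.condition_a}"

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def call_degs(
    result: DEResult, fold_cutoff: float = 2.0, alpha: float = 0.1
) -> DEGSet:
    """Threshold a DE table into up/down gene sets (strict inequalities)."""
    if fold_cutoff <= 1.0:
        raise UsageError("fold_cutoff must be > 1")
    if not 0.0 < alpha <= 1.0:
        raise UsageError("alpha must lie in (0, 1]")
    t = result.table
    lfc = np.log2(fold_cutoff)
    sig = t["padj"] < alpha  # NaN compares False
    up = frozenset(t.index[sig & (t["log2fc"] > lfc)])
    down = frozenset(t.index[sig & (t["log2fc"] < -lfc)])
    return DEGSet(result.condition_b, result.condition_a, up, down, fold_cutoff, alpha)


def unique_degs(treated: DEGSet, untreated: DEGSet) -> DEGSet:
    """Genes differential in ``treated`` but not in ``untreated``.

    Both sets must be contrasts against the same reference condition.
    Removal is by gene id regardless of direction: a gene that moved in the
    untreated contrast in *either* direction is excluded.
    """
    if treated.condition_a != untreated.condition_a:
        raise UsageError(
            f"mismatched reference conditions "
            f"({treated.condition_a!r} vs {untreated.condition_a!r})"
        )
    shared = untreated.genes
    return DEGSet(
        treated.condition_b,
        treated.condition_a,
        treated.up - shared,
        treated.down - shared,
        treated.fold_cutoff,
        treated.alpha,
    )


# ---------------------------------------------------------------------------
# DE table I/O
# ---------------------------------------------------------------------------


def write_de_table(result: DEResult, path) -> None:
    out = result.table.rename_axis("gene")
    out.to_csv(path, sep="\t", na_rep="NA")


def read_de_table(path, condition_b: str, condition_a: str) -> DEResult:
    """Load an externally computed DE table (gene, base_mean, log2fc, pvalue, padj)."""
    t = pd.read_csv(path, sep="\t", index_col="gene", na_values=["NA"], comment="#")
    for col in ("base_mean", "log2fc", "pvalue", "padj"):
        if col not in t.columns:
            raise UsageError(f"DE table missing column {col!r}")
    return DEResult(condition_b, condition_a, t)
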