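"""Rank statistics: per-gene lagged Spearman correlation between omics layers,
polysome occupancy, and the nonparametric tests used throughout the pipeline.

All cross-layer correlations are computed per gene across replicate-matched
samples (time-point t of layer A paired with time-point t+lag of layer B,
same replicate), so a lag-k correlation over T time-points and R replicates
uses (T-k) x R pairs per gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, average-rank ties).

    Pairs with a missing entry in either vector are dropped first.  Returns
    NaN (with a warning, not an error) if fewer than 3 complete pairs remain
    or if either vector is constant after filtering.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        warnings.warn("spearman_rho: fewer than 3 complete pairs; returning NaN",
                      stacklevel=2)
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def ranksum_test(a, b, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test for two independent samples.

    ``alternative='greater'`` tests whether values in ``a`` tend to be larger
    than values in ``b``.  Exact enumeration is used when n_a + n_b <= 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction.  Returns (U statistic of ``a``, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def signedrank_test(diffs, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Exact null enumeration for n <= 12 nonzero
    differences with no tied magnitudes; otherwise the normal approximation
    with tie and continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 3:
        raise ValueError("need at least 3 nonzero differences")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    mags = np.abs(d)
    has_ties = np.unique(mags).size < mags.size
    method = "exact" if (d.size <= 12 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alt, method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def shapiro_normality(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); reporting only, no branching."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Lagged per-gene layer correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    """Per-gene Spearman rho between two layers at a fixed contrast lag."""

    layer_pair: tuple[str, str]
    lag: int
    gene_ids: list[str]
    rho: np.ndarray          # NaN where undefined
    n_pairs: np.ndarray      # complete pairs used per gene

    @property
    def mean_rho(self) -> float:
        return float(np.nanmean(self.rho)) if np.isfinite(self.rho).any() else float("nan")

    @property
    def median_rho(self) -> float:
        return float(np.nanmedian(self.rho)) if np.isfinite(self.rho).any() else float("nan")

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.rho).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_ids,
            "layer_pair": f"{self.layer_pair[0]}->{self.layer_pair[1]}",
            "lag": self.lag,
            "rho": self.rho,
            "n_pairs": self.n_pairs,
        })


def _lagged_pair_matrices(a: ExpressionSet, b: ExpressionSet, lag: int):
    """Stack replicate-matched (t, t+lag) sample pairs of two layers.

    Returns (xa, xb) value matrices with NaN at undetected entries, columns
    ordered time-major over the (T - lag) leading time-points.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene universes differ between layers")
    times = a.times
    if times != b.times:
        raise ValueError("time grids differ between layers")
    if a.replicates != b.replicates:
        raise ValueError("replicate structure differs between layers")
    T = len(times)
    if not 0 <= lag < T:
        raise ValueError(f"lag must be in [0, {T - 1}]")
    cols_a, cols_b = [], []
    for i in range(T - lag):
        ca = a.sample_columns(times[i])
        cb = b.sample_columns(times[i + lag])
        if len(ca) != len(cb):
            raise ValueError("mismatched replicate counts between layers")
        cols_a.append(ca)
        cols_b.append(cb)
    ca = np.concatenate(cols_a)
    cb = np.concatenate(cols_b)
    xa = np.where(a.detected[:, ca], a.values[:, ca], np.nan)
    xb = np.where(b.detected[:, cb], b.values[:, cb], np.nan)
    return xa, xb


def per_gene_layer_correlation(a: ExpressionSet, b: ExpressionSet,
                               lag: int = 0) -> CorrelationSummary:
    """Per-gene Spearman correlation of layer ``a`` at t with ``b`` at t+lag.

    Pairs are replicate-matched; pairs with an undetected entry on either
    side are dropped; genes with fewer than 3 usable pairs (or a constant
    profile) get NaN and are excluded from summary statistics.
    """
    xa, xb = _lagged_pair_matrices(a, b, lag)
    n = a.n_genes
    rho = np.full(n, np.nan)
    npairs = np.zeros(n, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in range(n):
            ok = np.isfinite(xa[g]) & np.isfinite(xb[g])
            npairs[g] = int(ok.sum())
            if npairs[g] >= 3:
                rho[g] = spearman_rho(xa[g][ok], xb[g][ok])
    n_undef = int(np.isnan(rho).sum())
    if n_undef:
        log.info("per_gene_layer_correlation(%s->%s, lag=%d): %d/%d genes undefined",
                 a.layer, b.layer, lag, n_undef, n)
    return CorrelationSummary(layer_pair=(a.layer, b.layer), lag=lag,
                              gene_ids=list(a.gene_ids), rho=rho, n_pairs=npairs)


def polysome_occupancy(total: ExpressionSet, poly: ExpressionSet) -> ExpressionSet:
    """Polysome occupancy PO = log2(polysomal / total) per gene x sample.

    Values are already log2, so PO is the elementwise difference.  PO is a
    standard proxy for translational efficiency.  Defined only where both
    layers are detected.
    """
    if total.gene_ids != poly.gene_ids or total.values.shape != poly.values.shape:
        raise ValueError("total and polysomal sets must be shape-matched")
    t = total.reorder_time_major()
    p = poly.reorder_time_major()
    detected = t.detected & p.detected
    values = np.where(detected, p.values - t.values, np.nan)
    return ExpressionSet(gene_ids=list(t.gene_ids), layer="polysome_occupancy",
                         values=values, detected=detected,
                         sample_meta=t.sample_meta.copy())
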