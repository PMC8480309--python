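"""Consecutive-time-point differential expression with empirical-Bayes
variance moderation.

Per gene and layer a one-way group-means model over the detected time-points
gives time-point means, a pooled within-time residual variance s_g^2 with
d_g residual degrees of freedom, and one log2 fold change per consecutive
contrast (0->6, 6->26, 26->48, 48->72 HAI).  Variances are then shrunk
towards a common prior: the hierarchical model

    s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_{d_g} / d_g,
    1 / sigma_g^2     ~ chi^2_{d0} / (d0 * s0^2),

yields the posterior variance  s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
and a moderated t-statistic with d0 + d_g degrees of freedom.  The prior
(d0, s0^2) is estimated by moment-matching the distribution of log s_g^2
(digamma/trigamma inversion).  Significance is gated on |log2FC| > 1 and
Benjamini-Hochberg adjusted p < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import ExpressionSet

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NOTSIG = "notsig"


# ---------------------------------------------------------------------------
# Per-gene linear fit
# ---------------------------------------------------------------------------

@dataclass
class GeneFit:
    """Per-gene group-means fit for one layer.

    ``log2fc[g, c]`` is mean(t_{c+1}) - mean(t_c); ``v[g, c]`` the unscaled
    contrast variance factor 1/n1 + 1/n2; ``s2[g]`` the pooled within-time
    residual variance with ``df[g]`` degrees of freedom.  ``detected_both``
    marks contrasts with >= 2 detected replicates on both sides; only those
    are tested downstream.
    """

    gene_ids: list[str]
    layer: str
    contrasts: list[tuple[int, int]]
    log2fc: np.ndarray        # (G, C)
    v: np.ndarray             # (G, C) variance factor, NaN when untestable
    s2: np.ndarray            # (G,)
    df: np.ndarray            # (G,)
    detected_both: np.ndarray  # (G, C) bool


def fit_contrasts(x: ExpressionSet) -> GeneFit:
    """Fit the per-gene one-way model and all consecutive contrasts."""
    times = x.times
    if len(times) < 2:
        raise ValueError("need at least two time-points")
    G = x.n_genes
    T = len(times)
    vals = np.where(x.detected, x.values, np.nan)

    counts = np.empty((G, T), dtype=int)
    means = np.full((G, T), np.nan)
    ss = np.zeros(G)
    for j, t in enumerate(times):
        cols = x.sample_columns(t)
        block = vals[:, cols]
        n = np.isfinite(block).sum(axis=1)
        counts[:, j] = n
        means[:, j] = np.where(n > 0,
                               np.nansum(block, axis=1) / np.maximum(n, 1),
                               np.nan)
        resid = np.where(np.isfinite(block), block - means[:, j][:, None], 0.0)
        ss += np.nansum(resid * resid, axis=1)

    df = counts.sum(axis=1) - (counts > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, ss / np.maximum(df, 1), np.nan)

    C = T - 1
    contrasts = [(times[c], times[c + 1]) for c in range(C)]
    log2fc = np.full((G, C), np.nan)
    v = np.full((G, C), np.nan)
    detected_both = np.zeros((G, C), dtype=bool)
    for c in range(C):
        n1, n2 = counts[:, c], counts[:, c + 1]
        both1 = n1 >= 1
        both2 = n2 >= 1
        some = both1 & both2
        log2fc[some, c] = means[some, c + 1] - means[some, c]
        ok = (n1 >= 2) & (n2 >= 2)
        detected_both[:, c] = ok
        with np.errstate(divide="ignore"):
            v[ok, c] = 1.0 / n1[ok] + 1.0 / n2[ok]
    return GeneFit(gene_ids=list(x.gene_ids), layer=x.layer, contrasts=contrasts,
                   log2fc=log2fc, v=v, s2=s2, df=df.astype(float),
                   detected_both=detected_both)


# ---------------------------------------------------------------------------
# Empirical-Bayes shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from observed sample variances.

    Works on log s_g^2, whose mean and excess variance relative to the
    chi-squared sampling noise identify the prior.  Returns
    ``(inf, s0^2)`` when the variances show no excess dispersion.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual df and s2 > 0 "
                         "to estimate the variance prior")
    s2 = s2[ok]
    d = df[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1)
                 - np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if not np.isfinite(d0):
            return float("inf"), float(np.exp(emean))
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return float(d0), s0_sq
    return float("inf"), float(np.exp(emean))


@dataclass
class ModeratedStats:
    """Moderated t-statistics and p-values per gene x contrast."""

    gene_ids: list[str]
    layer: str
    contrasts: list[tuple[int, int]]
    d0: float
    s0_sq: float
    s2_tilde: np.ndarray      # (G,)
    df_total: np.ndarray      # (G,)
    log2fc: np.ndarray        # (G, C)
    t_mod: np.ndarray         # (G, C)
    p_raw: np.ndarray         # (G, C)
    p_adj: np.ndarray         # (G, C), BH per contrast
    detected_both: np.ndarray  # (G, C)


def ebayes_shrink(fit: GeneFit, d0: float | None = None,
                  s0_sq: float | None = None) -> ModeratedStats:
    """Shrink per-gene variances and compute moderated t / p-values.

    ``d0`` / ``s0_sq`` override the moment estimates (``d0=0`` reproduces the
    ordinary per-gene t-test; ``d0=inf`` pools every gene to the prior
    variance).  BH adjustment runs per contrast across genes.
    """
    informative = np.isfinite(fit.s2) & (fit.df > 0)
    if informative.any() and not np.any(fit.s2[informative] > 0):
        raise ValueError(
            "all residual variances are zero; the data look replicate-constant. "
            "Add measurement noise (jitter) or pass d0=float('inf') with an "
            "explicit s0_sq to override the prior.")
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(fit.s2, fit.df)
        if d0 is None:
            d0 = est_d0
        if s0_sq is None:
            s0_sq = est_s0
    d0 = float(d0)
    s0_sq = float(s0_sq)

    s2 = np.where(np.isfinite(fit.s2), fit.s2, 0.0)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    elif d0 == 0:
        s2_tilde = s2.copy()
        df_total = fit.df.copy()
    else:
        s2_tilde = (d0 * s0_sq + fit.df * s2) / (d0 + fit.df)
        df_total = d0 + fit.df

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_tilde[:, None] * fit.v)
        t_mod = fit.log2fc / se
    t_mod = np.where(fit.detected_both, t_mod, np.nan)

    p_raw = np.full_like(t_mod, np.nan)
    finite = np.isfinite(t_mod)
    dfb = np.broadcast_to(df_total[:, None], t_mod.shape)
    tt = np.abs(t_mod[finite])
    dd = dfb[finite]
    p = np.empty_like(tt)
    inf_df = np.isinf(dd)
    p[inf_df] = 2.0 * stats.norm.sf(tt[inf_df])
    p[~inf_df] = 2.0 * stats.t.sf(tt[~inf_df], dd[~inf_df])
    p_raw[finite] = p

    p_adj = np.column_stack([bh_adjust(p_raw[:, c]) for c in range(p_raw.shape[1])])
    return ModeratedStats(gene_ids=list(fit.gene_ids), layer=fit.layer,
                          contrasts=list(fit.contrasts), d0=d0, s0_sq=s0_sq,
                          s2_tilde=s2_tilde, df_total=df_total,
                          log2fc=fit.log2fc, t_mod=t_mod, p_raw=p_raw,
                          p_adj=p_adj, detected_both=fit.detected_both)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing (NaN) entries are propagated and excluded from the adjustment;
    input order is preserved; outputs are monotone in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    if q.size == 0:
        return out
    if np.any((q < 0) | (q > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = q.size
    order = np.argsort(q, kind="stable")
    ranked = q[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# Significance calls
# ---------------------------------------------------------------------------

@dataclass
class CallTable:
    """Up/down/notsig calls per gene x contrast, with an untested mask."""

    gene_ids: list[str]
    layer: str
    contrasts: list[tuple[int, int]]
    calls: np.ndarray      # (G, C) of {"up", "down", "notsig"}
    untested: np.ndarray   # (G, C) bool; untested contrasts are "notsig"

    def counts(self) -> pd.DataFrame:
        """Up/down/notsig/untested counts per contrast."""
        rows = []
        for c, (t0, t1) in enumerate(self.contrasts):
            col = self.calls[:, c]
            rows.append({
                "contrast": f"{t0}->{t1}",
                "up": int(np.sum(col == CALL_UP)),
                "down": int(np.sum(col == CALL_DOWN)),
                "notsig": int(np.sum((col == CALL_NOTSIG) & ~self.untested[:, c])),
                "untested": int(self.untested[:, c].sum()),
            })
        return pd.DataFrame(rows)


def call_de(m: ModeratedStats, lfc_min: float = 1.0, alpha: float = 0.05,
            use_adjusted: bool = True) -> CallTable:
    """Threshold moderated statistics into up/down/notsig calls.

    A gene is called at a contrast iff |log2FC| > ``lfc_min`` and the
    (adjusted, by default) p-value is below ``alpha``.  Contrasts lacking
    two detected replicates on either side are untested and reported as
    notsig with ``untested=True``.
    """
    if lfc_min < 0 or not 0 < alpha <= 1:
        raise ValueError("thresholds must be positive")
    pstar = m.p_adj if use_adjusted else m.p_raw
    sig = (pstar < alpha) & np.isfinite(pstar)
    calls = np.full(m.log2fc.shape, CALL_NOTSIG, dtype=object)
    calls[(m.log2fc > lfc_min) & sig] = CALL_UP
    calls[(m.log2fc < -lfc_min) & sig] = CALL_DOWN
    untested = ~m.detected_both
    calls[untested] = CALL_NOTSIG
    return CallTable(gene_ids=list(m.gene_ids), layer=m.layer,
                     contrasts=list(m.contrasts), calls=calls, untested=untested)


def de_results_frame(m: ModeratedStats, ct: CallTable) -> pd.DataFrame:
    """Long-format DE table: gene, contrast, log2fc, t_mod, p_raw, p_adj, call."""
    rows = []
    for c, (t0, t1) in enumerate(m.contrasts):
        rows.append(pd.DataFrame({
            "gene": m.gene_ids,
            "contrast": f"{t0}->{t1}",
            "log2fc": m.log2fc[:, c],
            "t_mod": m.t_mod[:, c],
            "p_raw": m.p_raw[:, c],
            "p_adj": m.p_adj[:, c],
            "call": ct.calls[:, c],
            "untested": ct.untested[:, c],
        }))
    return pd.concat(rows, ignore_index=True)
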