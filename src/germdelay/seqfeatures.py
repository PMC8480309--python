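"""Sequence-feature and decay-rate comparisons of delayed gene sets.

Compares a gene set (e.g. the DUG or DDG set) against the detected-proteome
background on mRNA/protein decay rates and region lengths (5'UTR, CDS,
3'UTR, full transcript).  The background deliberately *includes* the set,
mirroring the use of all identified protein-coding genes as background.
Given the skew of length and rate distributions, medians plus rank tests
are reported rather than means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import ranksum_test, signedrank_test
from .data_model import DecayTable, SequenceSet

log = logging.getLogger(__name__)

FEATURES = ("utr5_len", "cds_len", "utr3_len", "transcript_len",
            "mrna_decay", "mrna_half_life", "protein_decay")

_STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Significance bands: ns, then * / ** / *** / **** at 5e-2..1e-4."""
    for cut, stars in _STAR_BANDS:
        if p < cut:
            return stars
    return "ns"


def region_lengths(seqs: SequenceSet) -> pd.DataFrame:
    """Per-gene region lengths in nucleotides (empty regions give 0).

    Zero-length regions are kept in the table but excluded from that
    region's statistical comparisons by :func:`compare_feature` callers
    (a 0 means "no annotated region", not "length zero").
    """
    if len(seqs) == 0:
        raise ValueError("empty SequenceSet")
    rows = {}
    for gene in seqs.gene_ids:
        r = seqs[gene]
        rows[gene] = {
            "utr5_len": len(r.utr5),
            "cds_len": len(r.cds),
            "utr3_len": len(r.utr3),
            "transcript_len": len(r.full_transcript),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class FeatureComparison:
    feature: str
    gene_set: str
    n_set: int
    n_background: int
    median_set: float
    median_background: float
    statistic: float
    p: float
    stars: str

    def as_dict(self) -> dict:
        return dict(feature=self.feature, gene_set=self.gene_set,
                    n_set=self.n_set, n_background=self.n_background,
                    median_set=self.median_set,
                    median_background=self.median_background,
                    statistic=self.statistic, p=self.p, stars=self.stars)


def compare_feature(set_ids: Sequence[str], background_ids: Sequence[str],
                    values: Mapping[str, float] | pd.Series,
                    feature: str = "", gene_set: str = "set",
                    test: str = "ranksum",
                    rng: np.random.Generator | None = None) -> FeatureComparison:
    """Compare one numeric feature between a gene set and a background.

    ``values`` maps gene id -> value; missing / NaN values are dropped.  The
    default test is the unpaired rank-sum test (set vs background, two
    sided).  ``test='signedrank'`` instead pairs each set gene with a
    rank-matched background gene (nearest background value by rank, sampled
    without replacement) and runs the signed-rank test on the paired
    differences — a paired reading of a structurally unpaired comparison,
    provided for completeness.
    """
    vals = pd.Series(values, dtype=float)

    def extract(ids):
        x = vals.reindex([g for g in ids if g in vals.index]).to_numpy(float)
        return x[np.isfinite(x)]

    a = extract(set_ids)
    b = extract(background_ids)
    if a.size == 0:
        raise ValueError(f"gene set has no values for feature {feature!r}")
    if b.size == 0:
        raise ValueError(f"background has no values for feature {feature!r}")
    if test == "ranksum":
        stat, p = ranksum_test(a, b, alternative="two_sided")
    elif test == "signedrank":
        if rng is None:
            rng = np.random.default_rng(0)
        # rank-matched pairing: sort both, pair set genes with the background
        # quantile positions, subsample background without replacement
        bs = np.sort(b)
        pos = np.floor(np.linspace(0, b.size - 1, a.size)).astype(int)
        diffs = np.sort(a) - bs[pos]
        diffs = diffs[diffs != 0]
        if diffs.size < 3:
            stat, p = float("nan"), 1.0
        else:
            stat, p = signedrank_test(diffs, alternative="two_sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return FeatureComparison(
        feature=feature, gene_set=gene_set, n_set=int(a.size),
        n_background=int(b.size), median_set=float(np.median(a)),
        median_background=float(np.median(b)), statistic=float(stat),
        p=float(p), stars=significance_stars(float(p)))


def compare_all_features(set_ids: Sequence[str], background_ids: Sequence[str],
                         seqs: SequenceSet | None = None,
                         decay: DecayTable | None = None,
                         gene_set: str = "set",
                         test: str = "ranksum") -> pd.DataFrame:
    """Run every available feature comparison for one gene set.

    Length features come from ``seqs`` (genes with an empty region are
    excluded from that region's comparison), decay features from ``decay``.
    Features whose set values are entirely missing are skipped with a log
    entry.
    """
    feature_values: dict[str, pd.Series] = {}
    if seqs is not None:
        lens = region_lengths(seqs)
        for col in ("utr5_len", "cds_len", "utr3_len", "transcript_len"):
            s = lens[col].astype(float)
            feature_values[col] = s[s > 0]
    if decay is not None:
        t = decay.table
        feature_values["mrna_decay"] = t["mrna_decay_rate"].dropna()
        feature_values["mrna_half_life"] = t["mrna_half_life"].dropna()
        feature_values["protein_decay"] = t["protein_decay_rate"].dropna()
    rows = []
    for feat, vals in feature_values.items():
        try:
            rows.append(compare_feature(set_ids, background_ids, vals,
                                        feature=feat, gene_set=gene_set,
                                        test=test).as_dict())
        except ValueError as exc:
            log.info("skipping feature %s for set %s: %s", feat, gene_set, exc)
    return pd.DataFrame(rows)
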