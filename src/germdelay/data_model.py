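"""Core data containers and file I/O for the germination multi-omics pipeline.

The pipeline compares three molecular layers measured over the same seed
germination time course (0/dry, 6, 26, 48 and 72 hours after imbibition,
three biological replicates each): total mRNA, polysome-associated mRNA and
protein abundance (log2 LFQ).  This module defines the in-memory containers
for those layers plus gene-level sequence, decay-rate and annotation tables,
the text-file dialects they are exchanged in, the proteome detection filter,
and the descriptive bias summaries run before any differential analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

LAYERS = ("total_mRNA", "polysomal_mRNA", "protein")
DEFAULT_TIMES = (0, 6, 26, 48, 72)

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


# ---------------------------------------------------------------------------
# ExpressionSet
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSet:
    """A genes x samples log2 abundance matrix for one molecular layer.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    layer
        One of ``total_mRNA``, ``polysomal_mRNA``, ``protein`` (or a derived
        tag such as ``polysome_occupancy``).
    values
        float array, shape ``(n_genes, n_samples)``, log2 units.  Entries
        where ``detected`` is False may be NaN.
    detected
        boolean array, same shape; False marks a missing measurement
        (e.g. a protein below the LC-MS detection limit).  Missing values are
        carried as this mask and never imputed.
    sample_meta
        DataFrame with one row per sample and columns ``time_hai`` (int) and
        ``replicate`` (int, 1-based).
    """

    gene_ids: list[str]
    layer: str
    values: np.ndarray
    detected: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = pd.Series(self.gene_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected must have the same shape")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match gene_ids")
        if self.values.shape[1] != len(self.sample_meta):
            raise ValueError("column count does not match sample_meta")
        pairs = list(zip(self.sample_meta["time_hai"], self.sample_meta["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (time, replicate) sample")
        if self.n_times < 2:
            raise ValueError("an ExpressionSet needs at least two time-points")
        if not np.all(np.isfinite(self.values[self.detected])):
            raise ValueError("non-finite value at a detected entry")

    # -- convenience views ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def times(self) -> list[int]:
        """Sorted unique time-points (HAI)."""
        return sorted(self.sample_meta["time_hai"].unique().tolist())

    @property
    def n_times(self) -> int:
        return self.sample_meta["time_hai"].nunique()

    @property
    def replicates(self) -> list[int]:
        return sorted(self.sample_meta["replicate"].unique().tolist())

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_columns(self, time_hai: int) -> np.ndarray:
        """Column indices of all replicates of one time-point, replicate-sorted."""
        meta = self.sample_meta
        sel = meta.index[meta["time_hai"] == time_hai]
        reps = meta.loc[sel, "replicate"]
        return np.asarray(sel[np.argsort(reps.to_numpy(), kind="stable")])

    def reorder_time_major(self) -> "ExpressionSet":
        """Return a copy with samples ordered by (time, replicate)."""
        order = np.lexsort(
            (self.sample_meta["replicate"].to_numpy(), self.sample_meta["time_hai"].to_numpy())
        )
        return ExpressionSet(
            gene_ids=self.gene_ids,
            layer=self.layer,
            values=self.values[:, order],
            detected=self.detected[:, order],
            sample_meta=self.sample_meta.iloc[order].reset_index(drop=True),
        )

    def subset_genes(self, ids: Sequence[str]) -> "ExpressionSet":
        idx = self.gene_index()
        rows = [idx[g] for g in ids]
        return ExpressionSet(
            gene_ids=list(ids),
            layer=self.layer,
            values=self.values[rows],
            detected=self.detected[rows],
            sample_meta=self.sample_meta.copy(),
        )


def sample_name(time_hai: int, replicate: int) -> str:
    return f"{time_hai}_{replicate}"


_HEADER_RE = re.compile(r"^(\d+)_(\d+)$")


def read_expression_tsv(path, layer: str) -> ExpressionSet:
    """Read a genes x samples log2 matrix from TSV.

    Dialect: first column gene id; remaining column headers ``<time>_<replicate>``
    (e.g. ``6_2`` = 6 HAI, replicate 2); empty cells mean *not detected*;
    ``.`` decimal separator.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene-id column plus at least one sample")
    gene_ids = df.iloc[:, 0].tolist()
    times, reps = [], []
    for col in df.columns[1:]:
        m = _HEADER_RE.match(str(col).strip())
        if not m:
            raise ValueError(f"{path}: sample header {col!r} is not <time>_<replicate>")
        times.append(int(m.group(1)))
        reps.append(int(m.group(2)))
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    detected = np.vectorize(lambda s: str(s).strip() != "")(raw).astype(bool)
    values = np.full(raw.shape, np.nan)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i in range(raw.shape[0]):
            s = str(col[i]).strip()
            if s:
                try:
                    values[i, j] = float(s)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell {s!r} at gene {gene_ids[i]!r}, "
                        f"column {df.columns[j + 1]!r}"
                    ) from exc
    meta = pd.DataFrame({"time_hai": times, "replicate": reps})
    return ExpressionSet(gene_ids=gene_ids, layer=layer, values=values,
                         detected=detected, sample_meta=meta)


def write_expression_tsv(es: ExpressionSet, path) -> None:
    """Write an ExpressionSet in the dialect read by :func:`read_expression_tsv`.

    Undetected entries are written as empty cells, so write/read round-trips
    values, mask and metadata exactly (up to float formatting; ``repr``
    formatting keeps full precision).
    """
    cols = [sample_name(t, r) for t, r in
            zip(es.sample_meta["time_hai"], es.sample_meta["replicate"])]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for i, g in enumerate(es.gene_ids):
            cells = [repr(float(v)) if d else ""
                     for v, d in zip(es.values[i], es.detected[i])]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# SequenceSet
# ---------------------------------------------------------------------------

@dataclass
class GeneRegions:
    utr5: str = ""
    cds: str = ""
    utr3: str = ""

    @property
    def full_transcript(self) -> str:
        return self.utr5 + self.cds + self.utr3


@dataclass
class SequenceSet:
    """Per-gene 5'UTR / CDS / 3'UTR sequences, DNA alphabet (U already -> T)."""

    regions: dict[str, GeneRegions] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, gene: str) -> GeneRegions:
        return self.regions[gene]

    def region(self, gene: str, which: str) -> str:
        r = self.regions[gene]
        if which == "full":
            return r.full_transcript
        return getattr(r, which)


def _normalize_seq(seq: str, where: str) -> str:
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in {where}")
    return s


def _strip_splice(rec_id: str) -> str:
    # TAIR-style "AT1G01010.1" -> "AT1G01010"; ids without suffix pass through
    return re.sub(r"\.\d+$", "", rec_id)


def read_fasta_regions(utr5_path=None, cds_path=None, utr3_path=None) -> SequenceSet:
    """Read per-region FASTA files into a SequenceSet.

    Records may carry ``.<n>`` splice-form suffixes; only the first form
    encountered per gene is kept (representative splice form).  ``U`` is
    mapped to ``T``.  Genes absent from a region file get an empty string for
    that region; the gene universe is the union over the three files.
    """
    paths = {"utr5": utr5_path, "cds": cds_path, "utr3": utr3_path}
    out: dict[str, GeneRegions] = {}
    for which, path in paths.items():
        if path is None:
            continue
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fasta"):
            gene = _strip_splice(rec.id)
            if gene in seen:
                continue  # keep first splice form only
            seen.add(gene)
            seq = _normalize_seq(str(rec.seq), f"{which} record {rec.id}")
            if which == "cds" and not seq:
                raise ValueError(f"empty CDS for gene {gene!r}")
            out.setdefault(gene, GeneRegions())
            setattr(out[gene], which, seq)
    return SequenceSet(regions=out)


def write_fasta_regions(seqs: SequenceSet, utr5_path, cds_path, utr3_path) -> None:
    for which, path in (("utr5", utr5_path), ("cds", cds_path), ("utr3", utr3_path)):
        with open(path, "w", encoding="utf-8") as fh:
            for gene, r in seqs.regions.items():
                s = getattr(r, which)
                if s:
                    fh.write(f">{gene}\n{s}\n")


# ---------------------------------------------------------------------------
# Decay / annotation tables
# ---------------------------------------------------------------------------

@dataclass
class DecayTable:
    """Per-gene first-order decay constants.

    Columns: ``mrna_decay_rate`` (1/h), ``mrna_half_life`` (h, = ln2/rate),
    ``protein_decay_rate`` (1/day).  Any field may be NaN.
    """

    table: pd.DataFrame  # index = gene id

    def __post_init__(self) -> None:
        t = self.table
        for col in ("mrna_decay_rate", "mrna_half_life", "protein_decay_rate"):
            if col not in t.columns:
                t[col] = np.nan
        rates = t[["mrna_decay_rate", "protein_decay_rate"]].to_numpy(float)
        if np.nanmin(rates, initial=0.0) < 0:
            raise ValueError("decay rates must be nonnegative")
        both = t["mrna_decay_rate"].notna() & t["mrna_half_life"].notna()
        if both.any():
            rate = t.loc[both, "mrna_decay_rate"].to_numpy(float)
            hl = t.loc[both, "mrna_half_life"].to_numpy(float)
            ok = rate > 0
            if not np.allclose(hl[ok], np.log(2) / rate[ok], rtol=0.01):
                raise ValueError("mrna_half_life inconsistent with mrna_decay_rate")

    @classmethod
    def read_tsv(cls, path) -> "DecayTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


@dataclass
class AnnotationTable:
    """Per-gene subcellular location and GO term sets."""

    location: dict[str, str] = field(default_factory=dict)
    go_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, terms in self.go_terms.items():
            if any(not t for t in terms):
                raise ValueError(f"empty GO term id for gene {g!r}")

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        """Read TSV with columns gene, subcellular_location, go_terms (';'-joined)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        loc, go = {}, {}
        for _, row in df.iterrows():
            g = row["gene"]
            if row.get("subcellular_location", ""):
                loc[g] = row["subcellular_location"]
            terms = row.get("go_terms", "")
            if terms:
                go[g] = frozenset(t for t in terms.split(";") if t)
        return cls(location=loc, go_terms=go)

    def write_tsv(self, path) -> None:
        genes = sorted(set(self.location) | set(self.go_terms))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene\tsubcellular_location\tgo_terms\n")
            for g in genes:
                fh.write(f"{g}\t{self.location.get(g, '')}\t"
                         f"{';'.join(sorted(self.go_terms.get(g, ())))}\n")


# ---------------------------------------------------------------------------
# Detection filter and descriptive summaries
# ---------------------------------------------------------------------------

def protein_detection_filter(prot: ExpressionSet) -> list[str]:
    """Genes detected in *all* replicates of at least one time-point.

    This is the identification rule used for the proteome: a protein counts
    as identified only if it was measured in every biological replicate at
    one or more germination stages.  Input gene order is preserved.
    """
    if prot.layer != "protein":
        raise ValueError(f"detection filter is proteome-specific, got layer {prot.layer!r}")
    keep = np.zeros(prot.n_genes, dtype=bool)
    for t in prot.times:
        cols = prot.sample_columns(t)
        keep |= prot.detected[:, cols].all(axis=1)
    return [g for g, k in zip(prot.gene_ids, keep) if k]


def subcellular_ratios(genes: Sequence[str], ann: AnnotationTable) -> dict[str, float]:
    """Fraction of genes per subcellular location (plus ``unannotated``).

    Fractions sum to 1 over the returned categories.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    counts: dict[str, int] = {}
    for g in genes:
        loc = ann.location.get(g, "unannotated")
        counts[loc] = counts.get(loc, 0) + 1
    n = len(genes)
    return {loc: c / n for loc, c in sorted(counts.items())}


def expression_bias_summary(full_set: ExpressionSet, subset_ids: Sequence[str]) -> dict:
    """Compare expression of a gene subset against the full layer.

    Used to quantify the detection bias of the proteome: genes whose protein
    was identified tend to be higher expressed at the mRNA and polysomal mRNA
    level than the expressed-gene population as a whole.  Per gene the mean
    over detected samples is taken; the subset distribution is compared to
    the full-set distribution with a two-sided Wilcoxon rank-sum test.
    """
    from .correlation import ranksum_test  # local import to avoid cycle

    subset_ids = list(subset_ids)
    if not subset_ids:
        raise ValueError("empty subset")
    idx = full_set.gene_index()
    missing = [g for g in subset_ids if g not in idx]
    if missing:
        raise ValueError(f"subset gene(s) not in full set: {missing[:5]}")
    with np.errstate(invalid="ignore"):
        vals = np.where(full_set.detected, full_set.values, np.nan)
        gene_means = np.nanmean(vals, axis=1)
    sub_means = gene_means[[idx[g] for g in subset_ids]]
    full_ok = gene_means[np.isfinite(gene_means)]
    sub_ok = sub_means[np.isfinite(sub_means)]
    stat, p = ranksum_test(sub_ok, full_ok, alternative="two_sided")
    return {
        "layer": full_set.layer,
        "n_subset": len(sub_ok),
        "n_full": len(full_ok),
        "median_subset": float(np.median(sub_ok)),
        "median_full": float(np.median(full_ok)),
        "statistic": float(stat),
        "p_value": float(p),
    }
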