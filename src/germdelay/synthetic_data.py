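"""Synthetic multi-omics generator with planted delayed-response structure.

Emulates the germination study design — five physiological stages (dry seed
= 0, then 6, 26, 48 and 72 hours after imbibition) measured in three
biological replicates on three layers (total mRNA, polysomal mRNA, protein)
— with known ground truth so every downstream stage can be scored:

* gene trajectories are piecewise-constant (a single log2 step of size
  ``effect`` at a planted contrast), the minimal structure visible to a
  consecutive-contrast differential-expression analysis;
* ``delayed_up`` / ``delayed_down`` genes carry the same step on the protein
  layer shifted 1-3 contrasts later; ``concordant`` genes step on all layers
  at the same contrast; ``protein_only`` genes step on the protein layer
  only; ``null`` genes are flat;
* proteome detection dropout is an abundance-dependent logistic, emulating
  the LC-MS detection limit that biases the identified proteome towards
  highly expressed genes;
* sequences carry class-dependent region lengths and a planted 5'UTR motif;
  decay tables carry class-dependent rate distributions.

All generators are bit-reproducible given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (AnnotationTable, DecayTable, ExpressionSet, GeneRegions,
                         SequenceSet, write_expression_tsv, write_fasta_regions)

CLASSES = ("null", "concordant", "delayed_up", "delayed_down", "protein_only")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with germination-like defaults."""

    n_genes: int = 2000
    class_props: dict = field(default_factory=lambda: {
        "null": 0.70, "concordant": 0.10,
        "delayed_up": 0.15, "delayed_down": 0.05, "protein_only": 0.0,
    })
    times: tuple = (0, 6, 26, 48, 72)
    replicates: int = 3
    noise_sd: dict = field(default_factory=lambda: {
        "total_mRNA": 0.3, "polysomal_mRNA": 0.3, "protein": 0.3,
    })
    baseline_mean: float = 8.0     # log2 abundance
    baseline_sd: float = 2.0
    effect: float = 2.0            # log2 step size for non-null genes
    lag_choices: tuple = (1, 2, 3)  # delay in contrasts for delayed classes
    # planted change positions: keep contrast + lag on the grid by default
    restrict_change_to_grid: bool = True
    # proteome dropout: P(detected) = logistic((mean - midpoint) / slope)
    detect_midpoint: float = 5.0
    detect_slope: float = 1.5
    # sequences
    motif: str = "TCTTCTTC"
    plant_target: float = 0.4      # motif rate in delayed_up 5'UTRs
    plant_background: float = 0.05
    gc_content: float = 0.4
    utr5_meanlog: float = 4.8      # ~120 nt
    cds_meanlog: float = 7.1       # ~1200 nt
    utr3_meanlog: float = 5.3      # ~200 nt
    len_sdlog: float = 0.45
    cds_ratio_delayed_up: float = 0.6   # shorter CDS in the delayed-up class
    min_region_len: int = 20
    # decay rates (log-normal); mRNA per hour, protein per day
    mrna_decay_meanlog: float = float(np.log(0.12))
    protein_decay_meanlog: float = float(np.log(0.10))
    decay_sdlog: float = 0.6
    mrna_decay_mult: dict = field(default_factory=lambda: {"delayed_down": 2.0})
    protein_decay_mult: dict = field(default_factory=lambda: {"delayed_up": 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_props.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_props) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class(es): {sorted(unknown)}")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be positive")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        delayed = (self.class_props.get("delayed_up", 0)
                   + self.class_props.get("delayed_down", 0))
        if delayed > 0 and len(self.times) < 3:
            raise ValueError("delayed classes need at least 3 time-points")

    # -- YAML round-trip -----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["times"] = list(d["times"])
        d["lag_choices"] = list(d["lag_choices"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["times"] = tuple(d["times"])
        d["lag_choices"] = tuple(d["lag_choices"])
        return cls(**d)


@dataclass
class TruthLabels:
    """Ground truth of one synthetic run (one row per gene).

    Columns: ``klass``, ``lag`` (contrasts; 0 unless delayed), ``effect``
    (log2, 0 iff null), ``change_contrast`` (1-based first polysomal change;
    0 for null/protein_only), ``protein_contrast`` (1-based first protein
    change; 0 if none on the grid), ``observable`` (False when the planted
    protein change falls off the time grid), ``motif_planted``.
    """

    table: pd.DataFrame  # index = gene id

    def genes_of_class(self, klass: str) -> list[str]:
        return self.table.index[self.table["klass"] == klass].tolist()

    def class_counts(self) -> dict[str, int]:
        return self.table["klass"].value_counts().to_dict()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path) -> "TruthLabels":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def _class_counts(props: dict, n: int) -> dict[str, int]:
    """Largest-remainder rounding of proportions to integer counts."""
    raw = {k: props.get(k, 0.0) * n for k in CLASSES}
    counts = {k: int(np.floor(v + 1e-9)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(CLASSES, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_multiomics(cfg: SimConfig):
    """Simulate (total, polysomal, protein) ExpressionSets plus TruthLabels."""
    rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_genes
    T = len(cfg.times)
    C = T - 1
    R = cfg.replicates
    genes = _gene_ids(n)

    counts = _class_counts(cfg.class_props, n)
    klass = np.concatenate([[k] * counts[k] for k in CLASSES]).astype(object)
    rng.shuffle(klass)

    lag = np.zeros(n, dtype=int)
    delayed = np.isin(klass, ["delayed_up", "delayed_down"])
    lag[delayed] = rng.choice(cfg.lag_choices, size=int(delayed.sum()))

    changed = klass != "null"
    change = np.zeros(n, dtype=int)
    for i in np.where(changed)[0]:
        hi = C - lag[i] if cfg.restrict_change_to_grid else C
        hi = max(hi, 1)
        change[i] = rng.integers(1, hi + 1)

    sign = np.where(klass == "delayed_down", -1.0, 1.0)
    effect = np.where(changed, cfg.effect, 0.0) * sign
    prot_change = np.where(delayed, change + lag, change)
    observable = np.where(changed, prot_change <= C, False)
    prot_change = np.where(changed & (prot_change <= C), prot_change, 0)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    tidx = np.arange(T)
    step_rna = (tidx[None, :] >= change[:, None]) & changed[:, None] \
        & (klass != "protein_only")[:, None]
    step_prot = (prot_change[:, None] > 0) & (tidx[None, :] >= prot_change[:, None])
    rna_mean = baseline[:, None] + effect[:, None] * step_rna
    prot_mean = baseline[:, None] + effect[:, None] * step_prot

    meta = pd.DataFrame({
        "time_hai": np.repeat(cfg.times, R),
        "replicate": np.tile(np.arange(1, R + 1), T),
    })

    def layer(mean_gt: np.ndarray, name: str) -> np.ndarray:
        vals = np.repeat(mean_gt, R, axis=1)
        vals = vals + rng.normal(0.0, cfg.noise_sd[name], size=vals.shape)
        return vals

    total_vals = layer(rna_mean, "total_mRNA")
    poly_vals = layer(rna_mean, "polysomal_mRNA")
    prot_vals = layer(prot_mean, "protein")

    p_detect = 1.0 / (1.0 + np.exp(-(np.repeat(prot_mean, R, axis=1)
                                     - cfg.detect_midpoint) / cfg.detect_slope))
    prot_detected = rng.random(prot_vals.shape) < p_detect
    all_true = np.ones_like(total_vals, dtype=bool)

    total = ExpressionSet(genes, "total_mRNA", total_vals, all_true, meta.copy())
    poly = ExpressionSet(genes, "polysomal_mRNA", poly_vals, all_true.copy(), meta.copy())
    prot = ExpressionSet(genes, "protein",
                         np.where(prot_detected, prot_vals, np.nan),
                         prot_detected, meta.copy())

    truth = TruthLabels(pd.DataFrame({
        "klass": klass,
        "lag": lag,
        "effect": np.abs(effect),
        "change_contrast": np.where(klass == "protein_only", 0, change * changed),
        "protein_contrast": prot_change,
        "observable": observable,
        "motif_planted": np.zeros(n, dtype=bool),
    }, index=pd.Index(genes, name="gene")))
    return total, poly, prot, truth


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def generate_sequences(labels: TruthLabels, cfg: SimConfig) -> SequenceSet:
    """Simulate 5'UTR/CDS/3'UTR sequences with a planted 5'UTR motif.

    Region lengths are class-conditional log-normal (the delayed-up class
    gets CDSs shorter by ``cds_ratio_delayed_up``); the motif (DNA form of
    the planted element) is inserted at a uniform position of the 5'UTR with
    probability ``plant_target`` for delayed_up genes and
    ``plant_background`` otherwise.  ``motif_planted`` is recorded in the
    labels in place.
    """
    if len(labels.table) == 0:
        raise ValueError("empty labels")
    w = len(cfg.motif)
    if w > cfg.min_region_len:
        raise ValueError(f"motif ({w} nt) longer than minimum region length "
                         f"({cfg.min_region_len} nt)")
    rng = np.random.default_rng([cfg.seed, 2])
    regions: dict[str, GeneRegions] = {}
    planted = {}
    for gene, row in labels.table.iterrows():
        is_du = row["klass"] == "delayed_up"
        l5 = max(cfg.min_region_len,
                 int(rng.lognormal(cfg.utr5_meanlog, cfg.len_sdlog)))
        lc = max(cfg.min_region_len,
                 int(rng.lognormal(cfg.cds_meanlog, cfg.len_sdlog)
                     * (cfg.cds_ratio_delayed_up if is_du else 1.0)))
        lc = 3 * max(lc // 3, 10)  # CDS divisible by 3
        l3 = max(cfg.min_region_len,
                 int(rng.lognormal(cfg.utr3_meanlog, cfg.len_sdlog)))
        utr5 = _random_seq(rng, l5, cfg.gc_content)
        cds = _random_seq(rng, lc, cfg.gc_content)
        utr3 = _random_seq(rng, l3, cfg.gc_content)
        rate = cfg.plant_target if is_du else cfg.plant_background
        plant = bool(rng.random() < rate)
        if plant:
            pos = int(rng.integers(0, l5 - w + 1))
            utr5 = utr5[:pos] + cfg.motif + utr5[pos + w:]
        planted[gene] = plant
        regions[gene] = GeneRegions(utr5=utr5, cds=cds, utr3=utr3)
    labels.table["motif_planted"] = pd.Series(planted)
    return SequenceSet(regions=regions)


def generate_decay_tables(labels: TruthLabels, cfg: SimConfig) -> DecayTable:
    """Simulate class-conditional mRNA (1/h) and protein (1/day) decay rates."""
    if len(labels.table) == 0:
        raise ValueError("empty labels")
    for mult in (*cfg.mrna_decay_mult.values(), *cfg.protein_decay_mult.values()):
        if mult <= 0:
            raise ValueError("decay multipliers must be positive")
    rng = np.random.default_rng([cfg.seed, 3])
    n = len(labels.table)
    klass = labels.table["klass"].to_numpy()
    m_mult = np.array([cfg.mrna_decay_mult.get(k, 1.0) for k in klass])
    p_mult = np.array([cfg.protein_decay_mult.get(k, 1.0) for k in klass])
    mrna = rng.lognormal(cfg.mrna_decay_meanlog, cfg.decay_sdlog, n) * m_mult
    prot = rng.lognormal(cfg.protein_decay_meanlog, cfg.decay_sdlog, n) * p_mult
    df = pd.DataFrame({
        "mrna_decay_rate": mrna,
        "mrna_half_life": np.log(2) / mrna,
        "protein_decay_rate": prot,
    }, index=labels.table.index.copy())
    return DecayTable(df)


# GO terms / locations used by the synthetic annotation helper
_LOCATIONS = ("cytoplasm", "chloroplast", "nucleus", "mitochondrion", "other")
_LOC_PROBS = (0.35, 0.25, 0.2, 0.1, 0.1)
GO_PLANTED_TERM = "GO:0006412"  # translation; enriched in the delayed-up set


def generate_annotations(labels: TruthLabels, cfg: SimConfig,
                         n_terms: int = 20, planted_rate: float = 0.4,
                         background_rate: float = 0.08) -> AnnotationTable:
    """Simulate subcellular locations and flat GO term sets.

    One term (:data:`GO_PLANTED_TERM`) is planted in delayed_up genes at
    ``planted_rate`` vs ``background_rate`` elsewhere so GO enrichment has a
    known positive; the remaining terms are assigned independently of class.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    loc, go = {}, {}
    for gene, row in labels.table.iterrows():
        loc[gene] = _LOCATIONS[rng.choice(len(_LOCATIONS), p=_LOC_PROBS)]
        mine = {t for t in terms if rng.random() < 0.10}
        rate = planted_rate if row["klass"] == "delayed_up" else background_rate
        if rng.random() < rate:
            mine.add(GO_PLANTED_TERM)
        if mine:
            go[gene] = frozenset(mine)
    return AnnotationTable(location=loc, go_terms=go)


def write_fixture(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Generate a full synthetic study and write it in the pipeline's file
    dialects (TSV matrices, per-region FASTA, decay/annotation TSV, truth TSV,
    YAML config).  Returns the path of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    total, poly, prot, truth = generate_multiomics(cfg)
    seqs = generate_sequences(truth, cfg)
    decay = generate_decay_tables(truth, cfg)
    ann = generate_annotations(truth, cfg)
    paths = {
        "total": outdir / "total_mRNA.tsv",
        "polysomal": outdir / "polysomal_mRNA.tsv",
        "protein": outdir / "protein.tsv",
        "utr5": outdir / "utr5.fa",
        "cds": outdir / "cds.fa",
        "utr3": outdir / "utr3.fa",
        "decay": outdir / "decay.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_expression_tsv(total, paths["total"])
    write_expression_tsv(poly, paths["polysomal"])
    write_expression_tsv(prot, paths["protein"])
    write_fasta_regions(seqs, paths["utr5"], paths["cds"], paths["utr3"])
    decay.write_tsv(paths["decay"])
    ann.write_tsv(paths["annotations"])
    truth.write_tsv(paths["truth"])
    cfg.to_yaml(paths["config"])
    return paths
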