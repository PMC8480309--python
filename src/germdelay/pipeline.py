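"""End-to-end orchestration: from matrices (real files or the synthetic
generator) to the full report bundle.

Stages, in order: proteome detection filter and bias summaries; per-layer
moderated-t differential expression between consecutive time-points; lagged
polysome/total -> protein correlation; delayed-response (DUG/DDG)
classification; sequence-feature and decay comparisons; motif scanning and
motif/GO enrichment.  Every run writes TSV tables, a metrics.json and a
manifest with the config hash and seed, so runs are self-describing and
bit-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import per_gene_layer_correlation, polysome_occupancy
from .data_model import (AnnotationTable, DecayTable, ExpressionSet,
                         SequenceSet, expression_bias_summary,
                         protein_detection_filter, read_expression_tsv,
                         read_fasta_regions, subcellular_ratios)
from .delay import (classify_delay, delay_correlation_enhancement,
                    delayed_fraction, score_against_truth, shifted_profiles)
from .diffexpr import call_de, de_results_frame, ebayes_shrink, fit_contrasts
from .enrichment import (fisher_enrichment, go_enrichment, hits_frame,
                         kmer_discovery, load_meme_pwm, motif_gene_sets,
                         pwm_from_consensus, pwm_scan)
from .seqfeatures import compare_all_features
from .synthetic_data import (SimConfig, TruthLabels, generate_annotations,
                             generate_decay_tables, generate_multiomics,
                             generate_sequences)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``sim`` (synthetic study) or ``inputs`` (paths to TSV /
    FASTA files, keys: total, polysomal, protein, and optionally utr5, cds,
    utr3, decay, annotations, truth) must be set.
    """

    sim: SimConfig | None = None
    inputs: dict | None = None
    lfc_min: float = 1.0
    alpha: float = 0.05
    use_adjusted: bool = True
    lags: tuple = (0, 1, 2)
    any_later_change: bool = False
    motif_files: list = field(default_factory=list)
    motifs: list = field(default_factory=list)   # consensus strings
    motif_region: str = "utr5"
    outdir: str = "germdelay_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("set exactly one of sim / inputs")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    """Materialise (total, poly, prot, seqs, decay, ann, truth) from either source."""
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        total, poly, prot, truth = generate_multiomics(sim)
        seqs = generate_sequences(truth, sim)
        decay = generate_decay_tables(truth, sim)
        ann = generate_annotations(truth, sim)
        return total, poly, prot, seqs, decay, ann, truth
    paths = cfg.inputs
    total = read_expression_tsv(paths["total"], "total_mRNA")
    poly = read_expression_tsv(paths["polysomal"], "polysomal_mRNA")
    prot = read_expression_tsv(paths["protein"], "protein")
    seqs = None
    if all(k in paths for k in ("utr5", "cds", "utr3")):
        seqs = read_fasta_regions(paths["utr5"], paths["cds"], paths["utr3"])
    decay = DecayTable.read_tsv(paths["decay"]) if "decay" in paths else None
    ann = (AnnotationTable.read_tsv(paths["annotations"])
           if "annotations" in paths else None)
    truth = TruthLabels.read_tsv(paths["truth"]) if "truth" in paths else None
    return total, poly, prot, seqs, decay, ann, truth


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s done in %.2fs", name, t1 - t0)
    return t1


def run_pipeline(cfg: PipelineConfig, write_plots: bool = True) -> dict:
    """Run the full analysis; write the report bundle to ``cfg.outdir``.

    Returns a report dict with every intermediate table and a ``metrics``
    sub-dict (also written as metrics.json).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report: dict = {}
    metrics: dict = {"seed": cfg.seed}

    try:
        total, poly, prot, seqs, decay, ann, truth = _load_inputs(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage load: {exc}") from exc
    t0 = _stage("load", t0)

    # -- detection filter and bias summaries (identified-proteome report) ----
    detected = protein_detection_filter(prot)
    if not detected:
        raise RuntimeError("stage filter: no gene passes the detection filter")
    metrics["n_genes"] = total.n_genes
    metrics["n_proteins_detected"] = len(detected)
    bias = [expression_bias_summary(total, detected),
            expression_bias_summary(poly, detected)]
    report["bias_summary"] = pd.DataFrame(bias)
    report["bias_summary"].to_csv(outdir / "bias_summary.tsv", sep="\t", index=False)
    if ann is not None:
        ratios_all = subcellular_ratios(total.gene_ids, ann)
        ratios_det = subcellular_ratios(detected, ann)
        locs = sorted(set(ratios_all) | set(ratios_det))
        report["subcellular_ratios"] = pd.DataFrame({
            "location": locs,
            "fraction_all": [ratios_all.get(l, 0.0) for l in locs],
            "fraction_detected": [ratios_det.get(l, 0.0) for l in locs],
        })
        report["subcellular_ratios"].to_csv(outdir / "subcellular_ratios.tsv",
                                            sep="\t", index=False)
    t0 = _stage("filter", t0)

    # -- differential expression per layer ------------------------------------
    calls = {}
    for es in (total, poly, prot):
        fit = fit_contrasts(es)
        mod = ebayes_shrink(fit)
        ct = call_de(mod, lfc_min=cfg.lfc_min, alpha=cfg.alpha,
                     use_adjusted=cfg.use_adjusted)
        calls[es.layer] = ct
        de_results_frame(mod, ct).to_csv(outdir / f"de_{es.layer}.tsv",
                                         sep="\t", index=False)
        report[f"de_counts_{es.layer}"] = ct.counts()
        metrics[f"d0_{es.layer}"] = mod.d0
        metrics[f"s0_sq_{es.layer}"] = mod.s0_sq
    de_counts = pd.concat(
        [report[f"de_counts_{l}"].assign(layer=l) for l in calls])
    de_counts.to_csv(outdir / "de_counts.tsv", sep="\t", index=False)
    report["de_counts"] = de_counts
    t0 = _stage("diffexpr", t0)

    # -- lagged correlations on the detected-proteome subset ------------------
    total_d = total.subset_genes(detected)
    poly_d = poly.subset_genes(detected)
    prot_d = prot.subset_genes(detected)
    enh = delay_correlation_enhancement(total_d, poly_d, prot_d, lags=cfg.lags)
    corr_rows = []
    for (layer, lag), summ in enh["summaries"].items():
        corr_rows.append({"leading_layer": layer, "lag": lag,
                          "mean_rho": summ.mean_rho, "median_rho": summ.median_rho,
                          "n_genes_defined": summ.n_defined})
        summ.to_frame().to_csv(outdir / f"correlation_{layer}_lag{lag}.tsv",
                               sep="\t", index=False)
    report["correlation_summary"] = pd.DataFrame(corr_rows)
    report["correlation_summary"].to_csv(outdir / "correlation_summary.tsv",
                                         sep="\t", index=False)
    report["enhancement_tests"] = enh["tests"]
    for (layer, lag), res in enh["tests"].items():
        metrics[f"enhancement_{layer}_lag{lag}"] = res["enhancement"]
        metrics[f"enhancement_{layer}_lag{lag}_p"] = res["p"]
        metrics[f"mean_rho_{layer}_lag{lag}"] = res["mean_rho"]
        metrics[f"mean_rho_{layer}_lag0"] = res["mean_rho_lag0"]
    po = polysome_occupancy(total_d, poly_d)
    po_corr = per_gene_layer_correlation(po, prot_d.reorder_time_major(), 0)
    metrics["mean_rho_po_lag0"] = po_corr.mean_rho
    t0 = _stage("correlate", t0)

    # -- delayed-response classification --------------------------------------
    records = classify_delay(calls["polysomal_mRNA"], calls["protein"], detected,
                             any_later_change=cfg.any_later_change)
    records.to_csv(outdir / "delay_records.tsv", sep="\t", index=False)
    report["delay_records"] = records
    n_dug = int((records["klass"] == "DUG").sum())
    n_ddg = int((records["klass"] == "DDG").sum())
    metrics["n_dug"] = n_dug
    metrics["n_ddg"] = n_ddg
    metrics["delayed_fraction"] = delayed_fraction(records, len(detected))
    dug_genes = records.loc[records["klass"] == "DUG", "gene"].tolist()
    ddg_genes = records.loc[records["klass"] == "DDG", "gene"].tolist()
    (outdir / "dug_genes.txt").write_text("\n".join(dug_genes) + "\n")
    (outdir / "ddg_genes.txt").write_text("\n".join(ddg_genes) + "\n")
    delayed_ids = dug_genes + ddg_genes
    if delayed_ids:
        # correlation enhancement restricted to the delayed-response sets
        idx = {g: i for i, g in enumerate(detected)}
        rows = [idx[g] for g in delayed_ids]
        for lag in cfg.lags:
            if lag == 0:
                continue
            r0 = enh["summaries"][("polysomal_mRNA", 0)].rho[rows]
            rk = enh["summaries"][("polysomal_mRNA", lag)].rho[rows]
            ok = np.isfinite(r0) & np.isfinite(rk)
            if ok.sum() >= 3:
                metrics[f"enhancement_delayed_set_lag{lag}"] = float(
                    np.mean(rk[ok]) - np.mean(r0[ok]))
    profiles = shifted_profiles(records, poly_d, prot_d)
    profiles.to_csv(outdir / "shifted_profiles.tsv", sep="\t", index=False)
    report["shifted_profiles"] = profiles
    if truth is not None:
        scores = score_against_truth(records, truth)
        report["truth_scores"] = scores
        metrics["dug_ddg_sensitivity"] = scores["sensitivity"]
        metrics["dug_ddg_fdp"] = scores["fdp"]
    t0 = _stage("delay", t0)

    # -- sequence features / decay comparisons --------------------------------
    if seqs is not None or decay is not None:
        frames = []
        for label, ids in (("DUG", dug_genes), ("DDG", ddg_genes)):
            if ids:
                frames.append(compare_all_features(ids, detected, seqs=seqs,
                                                   decay=decay, gene_set=label))
        if frames:
            feat = pd.concat(frames, ignore_index=True)
            feat.to_csv(outdir / "feature_comparisons.tsv", sep="\t", index=False)
            report["feature_comparisons"] = feat
    t0 = _stage("seqfeat", t0)

    # -- motif scanning + enrichment -------------------------------------------
    if seqs is not None:
        pwms = []
        for mf in cfg.motif_files:
            pwms.extend(load_meme_pwm(mf))
        for consensus in cfg.motifs:
            pwms.append(pwm_from_consensus(consensus))
        if not pwms and cfg.sim is not None:
            pwms.append(pwm_from_consensus(cfg.sim.motif))
        motif_rows = []
        all_hits = []
        for pwm in pwms:
            # matched-sequence identification: raw p < 1e-4 cutoff
            hits = pwm_scan(pwm, seqs, cfg.motif_region, alpha_adj=None)
            all_hits.append(hits_frame(hits, pwm.motif_id))
            gene_sets = motif_gene_sets(hits)
            motif_genes = gene_sets.get(cfg.motif_region, [])
            background = list(total.gene_ids)  # expressed-mRNA background
            for label, ids in (("DUG", dug_genes), ("DDG", ddg_genes)):
                if not ids:
                    continue
                res = fisher_enrichment(ids, background, motif_genes,
                                        term=f"{pwm.motif_id}@{cfg.motif_region}")
                motif_rows.append({**res.as_dict(), "gene_set": label,
                                   "n_motif_genes": len(motif_genes)})
                metrics[f"motif_{pwm.motif_id}_{label}_p"] = res.p
        if all_hits:
            pd.concat(all_hits, ignore_index=True).to_csv(
                outdir / "motif_hits.tsv", sep="\t", index=False)
        if motif_rows:
            report["motif_enrichment"] = pd.DataFrame(motif_rows)
            report["motif_enrichment"].to_csv(outdir / "motif_enrichment.tsv",
                                              sep="\t", index=False)
        if dug_genes:
            target = {g: seqs.region(g, cfg.motif_region) for g in dug_genes
                      if g in seqs.regions}
            bg = {g: seqs.region(g, cfg.motif_region) for g in detected
                  if g not in set(dug_genes) and g in seqs.regions}
            if target and bg:
                km = kmer_discovery(target, bg)
                km.to_csv(outdir / "kmer_discovery.tsv", sep="\t", index=False)
                report["kmer_discovery"] = km
    if ann is not None:
        go_frames = []
        for label, ids in (("DUG", dug_genes), ("DDG", ddg_genes)):
            if not ids:
                continue
            try:
                g = go_enrichment(ids, detected, ann, alpha=cfg.alpha)
            except ValueError as exc:
                log.info("GO enrichment skipped for %s: %s", label, exc)
                continue
            go_frames.append(g.assign(gene_set=label))
        if go_frames:
            go_all = pd.concat(go_frames, ignore_index=True)
            go_all.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)
            report["go_enrichment"] = go_all
    t0 = _stage("enrich", t0)

    # -- metrics / manifest / plots --------------------------------------------
    metrics_json = json.dumps(metrics, indent=2, sort_keys=True, default=float)
    (outdir / "metrics.json").write_text(metrics_json)
    manifest = {
        "package": "germdelay",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "metrics_hash": hashlib.sha256(metrics_json.encode()).hexdigest(),
        "thresholds": {"lfc_min": cfg.lfc_min, "alpha": cfg.alpha,
                       "use_adjusted": cfg.use_adjusted},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report["metrics"] = metrics
    report["manifest"] = manifest
    if write_plots:
        try:
            _write_plots(report, outdir)
        except Exception as exc:  # plotting must never break the analysis
            log.warning("plotting failed: %s", exc)
    _stage("report", t0)
    return report


def _write_plots(report: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    dc = report["de_counts"]
    for layer, grp in dc.groupby("layer"):
        axes[0].plot(grp["contrast"], grp["up"] + grp["down"], marker="o",
                     label=layer)
    axes[0].set_xlabel("contrast (HAI)")
    axes[0].set_ylabel("differential genes")
    axes[0].legend(fontsize=8)
    cs = report["correlation_summary"]
    for layer, grp in cs.groupby("leading_layer"):
        axes[1].plot(grp["lag"], grp["mean_rho"], marker="o", label=f"{layer}->protein")
    axes[1].set_xlabel("lag (contrasts)")
    axes[1].set_ylabel("mean Spearman rho")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "summary.png", dpi=100)
    plt.close(fig)
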