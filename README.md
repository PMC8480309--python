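# germdelay

Multi-omics delay analysis of seed germination: does a gene's change in
**protein abundance** lag its change in **polysome association**?

During germination (dry seed, then 6, 26, 48 and 72 hours after imbibition,
HAI) transcriptome and translatome reprogram quickly, but many proteins only
follow one or more stages later. `germdelay` implements the complete analysis
chain for detecting and characterising this delay from three log2 abundance
matrices (total mRNA, polysomal mRNA, protein LFQ; genes × 15 samples = 5
time-points × 3 replicates), and ships a synthetic multi-omics generator
with planted ground truth so every stage can be validated end to end.

## What it computes

1. **Proteome identification filter** — a protein counts as identified only
   if detected in *all* replicates of at least one stage; expression-bias
   and subcellular-composition summaries of the identified subset.
2. **Differential expression between consecutive time-points** with
   empirical-Bayes variance moderation. Per gene, a one-way group-means
   model gives log2 fold changes β̂_gc = x̄_g(t_{c+1}) − x̄_g(t_c), a pooled
   residual variance s²_g with d_g degrees of freedom, and the moderated
   statistic

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t̃_gc = β̂_gc / √(s̃²_g · (1/n₁ + 1/n₂)),   t̃ ~ t(d₀ + d_g),

   with the prior (d₀, s₀²) estimated per layer by moment-matching
   log s²_g (digamma/trigamma inversion). Calls use |log2FC| > 1 and
   Benjamini–Hochberg adjusted p < 0.05 by default.
3. **Lagged cross-layer correlation** — per-gene Spearman ρ between layer A
   at t and layer B at t+lag (replicate-matched; lag in contrast units),
   plus polysome occupancy PO = log2(P/T).
4. **Delayed-response classification** — per gene, the first contrast with a
   significant polysomal change is matched to the first significant protein
   change; same direction with the protein 1–3 contrasts later ⇒ DUG
   (delayed up) or DDG (delayed down), with the offset recorded as the
   +1/+2/+3 shift. Reports the delayed fraction of the identified proteome
   and shift-aligned mean profiles.
5. **Sequence features and enrichment** — region lengths (5'UTR/CDS/3'UTR)
   and mRNA/protein decay-rate comparisons of the DUG/DDG sets against the
   identified-proteome background (rank-sum tests, medians); PWM scanning
   with *exact* position p-values (dynamic programming over an integerized
   score lattice); one-tailed Fisher motif enrichment; exhaustive k-mer
   ranking; flat GO-term enrichment against a custom background.

## Worked example

Run the full pipeline on the default synthetic study (2,000 genes, 300
delayed-up / 100 delayed-down / 200 concordant / 1,400 null, log2 effect
2.0, noise sd 0.3, abundance-dependent proteome dropout):

```bash
germdelay run-all --seed 1 --outdir out/
```

prints

```
proteins detected: 1839
DUG: 261  DDG: 52  delayed fraction: 0.170
```

i.e. 1,839 of 2,000 genes pass the identification filter; 261 + 52 = 313
genes are classified as delayed (17.0 % of the identified proteome — the
planted rate is 20 %, with the remainder lost to detection dropout at the
contrast being tested). `out/` then contains the DE tables per layer,
up/down counts per HAI pair, per-gene correlation tables at each lag, the
delay table with DUG/DDG lists and shift-aligned profiles, feature
comparisons, motif and GO enrichment tables, `metrics.json` and a manifest
with the config hash and seed. Against the generator's truth labels this
run recovers delayed genes with sensitivity 0.835 and false-discovery
proportion 0.0 (`metrics.json`: `dug_ddg_sensitivity`, `dug_ddg_fdp`).

The same study can be materialised as files (`germdelay simulate`) and
re-analysed from disk; both routes give bit-identical metrics.

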