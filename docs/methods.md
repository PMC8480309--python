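# Methods

## The problem

Seed germination is driven by stored and newly synthesised proteins whose
abundance changes are not a simple readout of their mRNAs: even
polysome-associated (actively translated) mRNA changes precede the
corresponding protein changes by one or more developmental stages.
`germdelay` operationalises this as a contrast-level question on a shared
time grid (0/dry, 6, 26, 48, 72 hours after imbibition; 3 biological
replicates; consecutive contrasts 0→6, 6→26, 26→48, 48→72): *at which
contrast does each gene first change on the polysomal layer, at which
contrast does its protein first change, and what is the offset ("shift")
between the two?*

## Differential expression with moderated variances

Each layer is analysed with a per-gene one-way group-means model over its
detected time-points. For gene g: per-time means from the detected
replicates; pooled within-time residual variance s²_g with
d_g = (detected samples) − (time-points with ≥ 1 detection) degrees of
freedom; per consecutive contrast the log2 fold change is the difference of
time-point means with variance factor v = 1/n₁ + 1/n₂. A contrast is
*testable* only when both sides have ≥ 2 detected replicates; missing
proteome values are carried as a mask and never imputed.

Gene variances are shrunk under the standard hierarchical model
s²_g | σ²_g ~ σ²_g χ²_{d_g}/d_g, 1/σ²_g ~ χ²_{d₀}/(d₀ s₀²), giving the
posterior s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g) and a moderated t with
d₀ + d_g degrees of freedom. The prior is estimated per layer (pooled over
contrasts) by moment-matching the mean and excess variance of log s²_g,
inverting the trigamma function by Newton iteration; when the observed
variances show no excess dispersion the estimator returns d₀ = ∞
(all genes pooled to s₀²). Overrides d₀ = 0 (ordinary per-gene t) and
d₀ = ∞ are exposed and tested. With replicate-constant data every s²_g is
zero and hyperparameter estimation is impossible; this raises an error
directing the user to jitter the data or set d₀ = ∞ explicitly.

Significance calls default to |log2FC| > 1 and BH-adjusted p < 0.05.
The phrase "p < 0.05 adjusted by the false discovery rate" admits two
readings (gate on adjusted p, or gate on raw p and report FDR); the gate is
on the adjusted p by default with `use_adjusted=False` exposing the other
reading. BH runs per contrast across genes — each consecutive-pair
comparison is its own testing family. Note BH is *not* idempotent
(re-adjusting adjusted values changes them; e.g. (0.25, 1.0) → (0.5, 1.0)
→ (1.0, 1.0)); the implementation is validated against a brute-force
step-up oracle instead.

## Delay classification

`first_change` returns the earliest significant contrast and its direction
(first event wins; all events are kept in an audit column). A gene in the
identified proteome is **DUG**/**DDG** when polysomal and protein
directions agree and the protein's first change is 1–3 contrasts later;
same contrast ⇒ *concordant*; opposite directions ⇒ *discordant*; protein
change without polysomal change ⇒ *protein_only*; otherwise *unchanged*.
A protein change at the same contrast is deliberately *not* delayed, and
direction concordance is required — opposite-direction pairs are surfaced
as an explicit class rather than silently excluded. An `any_later_change`
flag relaxes the protein event to the first same-direction change after the
polysomal one (the strict first-change reading is the default). The delayed
fraction is (#DUG + #DDG)/(identified proteome size); with the published
set sizes 425 and 93 over 1,469 proteins this is 35 %.

## Lagged correlation

Per-gene Spearman ρ (Pearson on mid-ranks, average-rank ties) between
layer A at time index i and layer B at i+lag, replicate-matched, over the
(T − lag) × R detected pairs; genes with < 3 usable pairs or a constant
profile are undefined and excluded from summaries (counts logged).
Polysome occupancy is the log-ratio P/T, the standard translational-
efficiency proxy. Rank-sum / signed-rank tests use exact enumeration for
n ≤ 12 without ties and the tie- and continuity-corrected normal
approximation otherwise; Shapiro–Wilk is reported as a descriptive gate for
preferring rank statistics, never branched on.

## Synthetic study design

The generator emulates the germination study with known truth:

* **Trajectories** are piecewise-constant: baseline ~ N(8, 2²) on the log2
  scale plus a single step of size `effect` (default 2.0) at a planted
  contrast; replicate noise sd 0.3 per layer. Steps are the minimal
  structure a consecutive-contrast DE analysis can see, so nothing beyond
  them is simulated. Delays are planted in contrast units (lags 1–3),
  matching the shift vocabulary of the analysis.
* **Class mix** (defaults): 70 % null, 10 % concordant, 15 % delayed-up,
  5 % delayed-down; counts are largest-remainder rounded so marginals are
  exact. Change contrasts are drawn uniformly over positions where
  contrast + lag fits the grid, so planted delays are observable by
  default; with `restrict_change_to_grid=False` the protein step may fall
  off the grid, in which case the gene is recorded as unobservable
  (truth keeps the planted lag) — such genes are excluded from the
  sensitivity denominator, as are proteins the detection filter never
  identifies: delayed-response sets are defined within the identified
  proteome.
* **Proteome dropout** is Bernoulli per gene × sample with probability
  logistic((mean abundance − 5.0)/1.5): ≈ 0.88 per sample at the baseline
  mean and ≈ 0.5 two standard deviations below, reproducing the
  abundance bias of LC-MS identification (higher-expressed genes are
  over-represented in the identified proteome). The midpoint/slope are
  deliberately milder than the real study's ≈ 7 % identification rate —
  they produce a clear, testable bias while leaving enough identified
  delayed genes to score recovery.
* **Sequences**: i.i.d. nucleotides at GC 0.40; region lengths
  class-conditional log-normal (5'UTR ≈ 120 nt, CDS ≈ 1,200 nt — × 0.6 for
  delayed-up genes —, 3'UTR ≈ 200 nt, σ_log 0.45, CDS forced to a multiple
  of 3), roughly Arabidopsis-like. The motif TCTTCTTC (DNA form of the
  U-rich element; all sequences are normalised U→T) is planted at a uniform
  5'UTR position in 40 % of delayed-up genes vs 5 % elsewhere.
* **Decay tables**: log-normal rates (mRNA ≈ 0.12/h, protein ≈ 0.10/day,
  σ_log 0.6) with class multipliers (delayed-down mRNA decay × 2,
  delayed-up protein decay × 0.5). **Annotations**: class-independent
  subcellular locations; one GO term planted in delayed-up genes at 40 %
  vs 8 % so enrichment has a known positive.
* Each generator draws from a single stream seeded from `SimConfig.seed`;
  identical seeds give bit-identical output, and the file round-trip
  (write fixture, re-read, re-run) reproduces the in-memory run exactly.

What the generator does **not** emulate: smooth kinetics or
synthesis/degradation mechanisms, probe-level microarray artefacts,
correlated replicate effects, monosome translation, and real sequence
composition beyond length/GC. Passing tests therefore demonstrate that the
*method* recovers planted contrast-level structure under realistic noise
and dropout — not that real germination data would yield the same rates.

### A known negative result

On the reference scenario the *whole-proteome* mean per-gene ρ
(polysome → protein) does not increase at lag 1 (measured median ≈ −0.02):
with step trajectories the 200 concordant genes lose about twice as much
correlation when misaligned by one contrast as a partially-misaligned
delayed gene regains, cancelling the gain of the 400 delayed genes.
The enhancement is cleanly positive when restricted to the delayed genes
(≈ +0.13 at lag 1, and per planted-lag alignment the modal recovered shift
equals the planted lag). The whole-set enhancement seen in real data
(≈ 0.35 → 0.41) reflects smooth, broadly-lagging protein trajectories that
a piecewise-constant generator intentionally does not model.

## Motif and enrichment machinery

PWMs are read/written in MEME minimal text format (probability rows
validated to sum to 1; pseudocount 1e-6 folded into log2-odds scores).
Scanning is sense-strand only — inputs are mRNA-derived regions. Position
p-values are **exact**: scores are integerized at ε = 1e-3 bits and the
null distribution of the window score under the 0-order background is built
by per-position convolution; Pr(score ≥ s) is a suffix sum. Equality with
exhaustive 4^w enumeration is verified for w ≤ 8. Hits pass a raw p < 1e-4
gate and, optionally, a BH (or Bonferroni) gate over all scanned positions.
For *matched-sequence identification* with short consensus motifs the
adjusted gate is disabled (the smallest attainable p for an 8-mer is the
background probability of its consensus word, ≈ 2e-5, which can never clear
an FDR of 1e-3 over a 10⁵-position scan); the adjusted gate is intended for
specificity scans with wide, information-rich matrices.

Gene-set enrichment (motif and GO) is the one-tailed hypergeometric tail of
the 2×2 set × annotation table, with the sample odds ratio (Haldane 0.5
correction on zero cells, flagged) and BH across terms; backgrounds are
explicit parameters (expressed-mRNA background for motifs,
identified-proteome background for GO, both overridable). De novo discovery
is a deterministic exhaustive k-mer ranking (k = 5–8): gene-level presence
Fisher-tested against the background set, BH across all tested k-mers, with
expected presence under a first-order (dinucleotide) Markov model of the
background reported — a documented simplification, not an EM motif model.

Feature comparisons (region lengths, decay rates) use the unpaired rank-sum
test with medians, with a rank-matched signed-rank option for a paired
reading; the background includes the tested set by design. The overlap
makes the test slightly conservative (measured rejection ≈ 0.025–0.03 at
nominal 0.05); calibration is verified on disjoint splits (≈ 0.055).

## Problem sizes and numerical choices

Simulation-based tests use the reference scenario (2,000 genes, 10 seeds)
and 300–1,000-gene variants for single-property checks; exact-test oracles
enumerate completely (2×2 tables to N = 30, rank tests to n = 12, PWM
windows to w = 8). Score-lattice granularity 1e-3 bits; BH ties broken by
stable sort (no effect on values); Spearman is undefined (excluded, logged)
for constant profiles. All randomness flows from explicit seeds; there is
no hidden entropy anywhere in the package.

## Limitations

* Contrast-level delay detection cannot separate delayed synthesis from
  delayed degradation, and cannot see delays shorter than the sampling
  interval or beyond the last time-point.
* The detection filter conditions all downstream sets on the identified
  proteome; with abundance-dependent dropout, down-regulated delayed genes
  near the detection limit are systematically harder to recover (recovery
  at effect 3.0 dips for the down class even as the up class saturates).
* GO enrichment is flat (no term-graph propagation); k-mer discovery is
  bounded at k ≤ 8 and will report overlapping shifts of a longer planted
  element.
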