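# Methods

This note documents the models, parameter choices and known limits of
`cd4tex`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis pipeline

**QC.** Cells are dropped when their mitochondrial fraction (genes with the
`MT-` symbol prefix) exceeds 5%, when they express fewer than
`min_genes_per_cell` genes (default 200; the stand-in for empty-droplet
removal, since filtered matrices have no ambient-RNA signal left to model),
or when their total count exceeds the `doublet_count_quantile` (default
0.99) of the input distribution — a transparent stand-in for a doublet
caller, which can be disabled (quantile 1.0) or replaced by an absolute
`max_counts`. A data-adaptive quantile cut cannot be idempotent (re-running
it on its own output moves the quantile), so the idempotence guarantee is
stated for absolute thresholds; `QCParams.max_counts` materializes the cut
for checkpointed re-runs.

**Normalization and reduction.** Log-normalization is
ln(1 + 10⁴·count/total). Variable genes are ranked by variance-stabilized
standardized variance: per-gene mean/variance on raw counts, a degree-2
polynomial fit of log₁₀ variance on log₁₀ mean as the expected variance,
standardized counts clipped at √N, ties broken by gene id. PCA (default 20
components) runs on the HVG-restricted matrix after per-gene
standardization clipped at ±10, with a full SVD so results are
deterministic. Clustering is Leiden (RB-configuration, resolution 1.0,
seeded) on a shared-nearest-neighbor graph (Jaccard overlap of 20-NN sets,
pruned below 1/15). Cluster markers use a two-sided Wilcoxon rank-sum with
normal approximation and tie correction, BH-adjusted within each cluster;
markers are reported at adjusted p < 0.05 and natural-log fold-change
(ln of pseudocounted expm1-means) > 0.25. A UMAP helper exists for visual
reporting only; no statistic or test depends on its coordinates.

**Annotation.** Clusters (not single cells) are assigned to the program —
Treg {FOXP3, CTLA4, IL2RA}, Tfh {CXCL13, TOX2, BCL6}, effector {GZMA, GZMB,
NKG7, IFNG}, naive {CCR7, IL7R} — with the highest mean marker z-score;
exact ties resolve Treg > Tfh > effector > naive for determinism.
Proliferative (MKI67, TYMS, MCM2) and heat-shock (HSPA1A, HSPA1B) sets are
auxiliary tags: the source cluster taxonomy lists the heat-shock and
proliferative clusters both as Treg-derived subtypes and inside the
effector meta-cluster; this implementation follows the final meta-cluster
membership, and the marker dictionary is user-overridable where that call
should go the other way. "DNAJB" is a gene-family prefix, not a symbol, and
is excluded from the default dictionary. Modules are a fixed function of
the program: effector/Tfh → Module 1, Treg → Module 2, naive → neither.

**Scoring and Tex calls.** Module scores follow the binned-background
construction (24 equal-frequency average-expression bins, 100 control genes
per panel gene, sampled without replacement within a bin where possible;
fresh seeded sampling per call). Scores are computed on the full
log-normalized gene universe, never the HVG subset, because the background
bins need all genes. Anchor panels are derived within the module's own
cells (Module 1 for PDCD1, Module 2 for TIGIT, Tfh for CXCL13): deriving on
all cells would let between-module differences masquerade as exhaustion
correlation. Zero-variance genes are excluded; the anchor never enters its
own panel; ties in correlation resolve by gene id. The Tex threshold is the
arithmetic mean score of the scored population with a strict `>` — cells
exactly at the mean are non-Tex. Missing panel genes are dropped with a
warning; only an empty panel is an error.

**Repertoire.** The clonotype key concatenates TRA v/j and TRB v/d/j gene
calls ("NA" for a missing chain); a CDR3-inclusive strict mode is available
by flag. Barcodes with multiple contigs per chain keep the highest-UMI
contig. Expansion bins partition clone sizes: single (X = 1), double
(X = 2), multiple (X > 2). Composition tables count cells, not clones.

**Statistics.** Welch's t (Satterthwaite df), Kruskal–Wallis with tie
correction, Pearson chi-square without continuity correction, Tukey HSD
(Tukey–Kramer SE, studentized-range p), and Pearson correlation with the
t-based p are implemented from their closed forms in `cd4tex.stats`, with
only distribution functions taken from scipy; the test suite verifies each
against scipy's independent high-level implementations to 1e-8. The
ratio-volume significance rule is the conjunction p < 0.05 AND R² > 0.25.
Tumor volume defaults to the ellipsoid caliper form V = π/6·L·W²; a
`literal` mode computes π/6·L·W, since the printed formula in the source
protocol is ambiguous about the exponent — both are one flag apart and
neither is asserted as ground truth.

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes, with
planted truth for every claim:

- **Programs.** Cells draw a meta-cluster from (Treg 0.40, Tfh 0.20,
  effector 0.25, naive 0.15). Each program's canonical markers plus 25
  synthetic program markers get a +1.5 natural-log effect in their own
  cells — enough for clustering to be solvable but not trivial.
- **Counts.** Gamma–Poisson (negative binomial, size r = 2) around
  mu = exp(baseline + effects) × lognormal library size (log-sd 0.35).
  Baselines are N(ln 0.2, 1) per gene; anchors, markers and planted panel
  genes sit at a mean of 2 counts/cell — receptor and effector transcripts
  detected reliably rather than at the dropout floor, which is what makes
  correlation-based panel derivation meaningfully testable.
- **Exhaustion factors.** Five latent factors (PDCD1+30 partners in
  Module 1, TIGIT+30 in Treg, CXCL13+30 in Tfh, the suppressive panel in
  Treg, the effective panel in effector) load with per-gene weights in
  [0.5, 1] on a_c = δ·(tex<sub>c</sub>·1[home population] + N(0, 0.25)).
  Scaling the Gaussian noise by δ makes δ = 0 an exact null (genes
  exchangeable, anchor correlations centered at zero) while δ > 0 keeps the
  Tex/non-Tex separation imperfect. Default Tex fractions are Treg 0.5,
  Tfh/effector 0.35, naive 0 — the immunosuppressive module is the more
  exhausted one, which also drives the module-level expansion contrast.
  Effect sizes are calibration choices, not estimates of any real cohort:
  the source data are not public, so the generator defines study
  conditions rather than reproducing a dataset.
- **Mitochondrial tail.** Thirteen `MT-` genes carry ~1.5% of counts;
  exactly `high_mito_cell_count` cells (default 7) are pushed above 5%
  mito fraction and every other cell is capped at ≤ 5%, making QC recovery
  exact by construction rather than probabilistic.
- **Clones.** Cells partition into clones with geometric sizes, p = 0.3
  for Tex-seeded clones vs 0.9 otherwise (mean sizes 3.3 vs 1.1). Each
  clone carries one V(D)J/CDR3 tuple; distinct clones never collide on the
  gene-call key, so size recovery is exact. One TRA and one TRB per cell —
  no dual-alpha cells, a deliberate simplification that keeps clonotype
  calling unambiguous.
- **In-vivo tables.** Per-arm log final volumes (control e^6.8 ≈ 900 mm³,
  treated ≈ 420–460 mm³, log-sd 0.3) with exponential growth curves
  rendered as length/width pairs (aspect 1.3); the log Tex-ratio shares a
  Gaussian component with log volume at correlation −0.9 by default, and
  treated arms have higher ratio means, so the pooled ratio–volume
  correlation is negative both within and between arms.

What the generator does **not** model: ambient RNA, batch effects, doublet
expression mixtures, dual TCR chains, isotype/chain-pairing noise, and any
real cohort's cell proportions or HPV biology (the HPV label is a
passthrough covariate). Passing tests therefore demonstrate that the
implementation recovers the structure it targets under its stated noise
model — not that the biological claims hold in any particular dataset.

## Numerical and design choices

- Determinism end to end: one global seed feeds the simulator, clustering,
  and control-gene sampling; full PCA SVD, sorted tie-breaks everywhere
  (gene ids for rankings, cluster size then label for relabeling, key
  strings for clonotype ids). Two runs of `run-all` with the same seed are
  byte-identical, which the acceptance suite checks.
- Null calibration of the Tex-contrast test is stated for groups that are
  independent of the scores (the planted labels at δ = 0, where "Tex" is a
  coin flip). Grouping cells by one module score and then testing a second
  score is mildly anticonservative even under the null, because both
  scores share the binned-background construction — an instance of
  selection-induced double dipping, observable with this generator by
  swapping the grouping in the calibration test.
- Degenerate inputs: all-tied score vectors classify everything non-Tex
  with a warning; all-tied groups give H = 0, p = 1; zero expected counts
  abort the chi-square with advice to merge bins; zero within-group
  variance aborts Tukey; caliper rows with width > length are swapped with
  a warning.
- Stage checkpoints store small tables (clusters, markers, panels, scores)
  and re-derive matrices from the simulated counts on demand, keeping
  run directories light and every subcommand independently invocable.
- Default problem sizes (3000 cells × 5000 genes for the demo and
  reference conditions; 400 × 1000 × 200 replicates for null calibration)
  were chosen so the planted effects are comfortably detectable while a
  full run stays in the tens of seconds on one CPU.

## Known limitations

- Cluster-level annotation cannot recover mixed clusters; cells of a
  minority program inside a cluster inherit the majority label.
- The derived TIGIT panel competes with the suppressive program planted in
  the same Treg-Tex cells, so Module-2 panel recovery is structurally a
  little lower than Module 1's — visible in the acceptance report.
- The mean-threshold Tex rule is scale-dependent by design (it follows the
  method being implemented), so Tex fractions are not comparable across
  populations scored separately.
- The in-vivo generator produces smooth exponential growth; it does not
  model measurement dropout, regressing tumors, or per-day noise.
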