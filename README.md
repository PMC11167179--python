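# cd4tex

Exhaustion-module analysis of tumor-infiltrating CD4⁺ T cells from
single-cell RNA-seq and paired single-cell TCR-seq.

Tumor-infiltrating CD4⁺ T cells split into functionally opposed
compartments: an immune-promoting **Module 1** (Tfh + effector programs,
marked by PDCD1) and an immunosuppressive **Module 2** (Treg program, marked
by TIGIT). Within each module, exhausted (Tex) cells can be identified by
scoring an anchor-correlated gene panel, and the two Tex compartments behave
differently — Treg-Tex cells are more suppressive and more clonally
expanded, effector-Tex cells more cytotoxic. `cd4tex` implements this
analysis as a reusable, tested pipeline for people who want to apply or
probe the method: from a 10x-dialect count matrix and VDJ contig table to
meta-cluster annotation, module scores, Tex calls, clonal-expansion
statistics and the accompanying mouse checkpoint-blockade statistics.
Because the method's behaviour is hard to audit on unlabeled real data, the
package ships a first-class synthetic-data generator that plants every
structure the pipeline claims to recover.

## The statistic at the core

For a gene panel *P* and cell *c* with log-normalized expression
*x<sub>cg</sub>* = ln(1 + 10⁴·count/total), the **module score** is

&nbsp;&nbsp;&nbsp;&nbsp;S(c) = mean<sub>g∈P</sub> x<sub>cg</sub> − mean<sub>g∈C</sub> x<sub>cg</sub>,

where the control set *C* pools, for each panel gene, 100 genes sampled from
that gene's average-expression bin (24 equal-frequency bins over all genes),
so the score is a background-corrected contrast rather than a raw mean.
Exhaustion panels are **derived**, not fixed: within a module's cells, the
top 30 genes by Pearson correlation with the anchor (PDCD1 for Module 1,
TIGIT for Module 2, CXCL13 for the Tfh chemotaxis panel) form the panel.
Cells whose exhaustion score strictly exceeds the population mean are called
**Tex**. Suppressive (TGFB1, IL10, IL12A, CTLA4, IKZF4, LGALS3, ENTPD1,
NT5E) and effective (IL17A, CD69, IFNG, IL4, IL5, IL13, IL17F, TNFRSF8,
PALLD, TNF) scores use fixed literature panels. Clonotypes are groups of
cells with identical TRA/TRB V(D)J gene calls, binned by clone size X as
single (X = 1), double (X = 2) or multiple (X > 2). Group contrasts use
Kruskal–Wallis (scores), Pearson chi-square (expansion bins), Welch's t
(MFI), Tukey HSD (tumor volumes, V = π/6·L·W²) and Pearson correlation with
the conjunction rule p < 0.05 AND R² > 0.25.

## Worked example

```bash
python examples/exhaustion_scoring.py
```

simulates 3000 cells × 5000 genes with a planted exhaustion factor
(log-effect δ = 1.0 on the PDCD1 partner block in Tex cells), derives the
Module-1 panel and calls Tex cells:

```
derived panel recovers 28/30 planted partner genes
Tex call balanced accuracy vs planted labels: 0.884
Kruskal-Wallis of score by planted label: H = 788.6, p = 1.62e-173
```

28/30 means the anchor correlation found nearly the entire planted
co-regulated block among 5000 genes; balanced accuracy 0.88 means the
mean-threshold Tex call separates planted exhausted cells well above chance
(0.5). The other scripts in `examples/` cover simulation
(`simulate_and_inspect.py`), repertoire analysis (`clonal_expansion.py`),
the mouse statistics (`invivo_analysis.py`) and the full checkpointed
pipeline (`full_pipeline.py`, equivalent to
`cd4tex run-all --outdir demo_run --seed 1`).

## Layout

- `src/cd4tex/` — `synthdata` (generator), `io_10x` (formats), `preprocess`
  (QC → clustering → markers), `annotate` (meta-clusters and modules),
  `scoring` (panels, module scores, Tex calls), `repertoire` (clonotypes),
  `invivo` (mouse statistics), `stats` (shared tests), `pipeline` + `cli`.
- `docs/methods.md` — model assumptions, parameter choices and limitations.
- `tests/` — unit, property and acceptance suites.
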