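# stagewire

Stage re-wiring analysis of cancer progression from multi-stage expression
cohorts.

Tumours do not only change *which* genes they express as they progress —
they change *how genes co-vary*.  `stagewire` reconstructs, for each disease
stage, a differential co-expression network that contrasts the stage's
correlation structure against all remaining samples, extracts the re-wired
gene modules, scores them for stage-specificity and disease relevance,
builds a survival risk model from the prognostic genes, and classifies every
strong gene-gene edge as *gained*, *lost*, or *reversed* between consecutive
stages.  It is aimed at systems-biology analysts who want a tested,
reproducible version of this workflow, with a fully seeded synthetic-data
generator that plants every kind of signal the pipeline is supposed to find.

## The method

Given a gene × sample count matrix and condition labels
`{normal, I, II, III, IV}`:

1. **Preprocessing** — drop NA/all-zero genes, drop genes with mean
   CPM < 0.5, drop the least-variable quartile by coefficient of variation,
   TMM-normalize to `log2(CPM + 1)`, and drop genes with scaled connectivity
   `k_i = Σ_{j≠i} |r_ij| / (G−1) < 0.1` on the pooled correlation network.
2. **Differential network** — per stage, Pearson adjacencies `C^stage` and
   `C^rest`, combined into the differential dissimilarity

   `d_ij = ( |sign(C^stage_ij)(C^stage_ij)² − sign(C^rest_ij)(C^rest_ij)²| / 2 )^(β/2)`,

   with β = 6, followed by a topological-overlap transform (clustering input
   is `1 − TOM(d)`).
3. **Modules** — average-linkage hierarchical clustering with an adaptive
   (dynamic-tree-cut-style) cut, PAM-like medoid reassignment, and merging
   of clusters closer than 0.2.
4. **Scoring** — each module gets `BCSS = SS + BCR + BCRNCR ∈ [0, 4]`:
   `SS = (1 − rescale(Zsummary)) + rescale(Medianrank)` from permutation
   preservation statistics (low `Zsummary` + high `Medianrank` ⇒
   stage-specific); `BCR = rescale(−log10 p)` of a one-sided Fisher
   enrichment of disease-associated coding genes; `BCRNCR` = fraction of the
   module's non-coding genes already reported in the disease.  The maximal
   module per stage is selected.
5. **Survival** — median-split Kaplan–Meier log-rank per gene (p < 0.05 ⇒
   prognostic); Kruskal–Wallis + Dunn (BH-adjusted) stage-trend
   classification into ascending / descending / outset-cancer; VIF-pruned
   (< 10) Cox proportional-hazards risk model; patients stratified at the
   Q1/Q3 quartiles of `exp(linear predictor)`; outset-cancer genes validated
   by a five-fold linear-kernel SVM separating normal from stage I.
6. **Re-wiring** — per-condition networks over prognostic genes thresholded
   at |r| ≥ 0.7; edges classified gain / loss / reversed between consecutive
   conditions; hub genes ranked by changed-edge degree; progression
   biomarkers ranked by five indices (prognostic, trend, hub, novelty,
   re-wiring breadth).

## Worked example

```bash
stagewire run-all --seed 1 --out out/
```

runs the whole pipeline on the default synthetic cohort (315 tumour samples
40/92/55/15 across stages I–IV plus 113 normals, four planted 50-gene
re-wired modules, survival hazard doubling per SD of the stage-I module
signature) and prints the module selected per stage:

```
{"I": "module_2", "II": "module_1", "III": "module_2", "IV": "module_2"}
```

`out/report.json` holds the full machine-readable report.  For seed 1 it
records, per stage, the selected module and its BCSS (e.g. stage II selects
a 40-gene module at BCSS 2.60, drawn from the module planted to re-wire in
stage II), 42 prognostic genes among the 127 candidate genes of the selected
modules, a Cox risk model with c-index 0.744 whose three risk strata
separate at log-rank p ≈ 1.8 × 10⁻²⁸, and the re-wiring counts per
transition — for seed 1 the normal→I transition is loss-dominated (85 lost
vs 9 gained edges, the planted stage-I module decorrelating) while III→IV is
gain-dominated (302 gained vs 6 lost).  Every artifact (counts, design,
normalized expression, per-stage modules, preservation tables, scores,
prognostic table, risk model, re-wiring edge lists) is written as plain
TSV/JSON, and the run is bit-reproducible for a fixed seed.

The same steps are available as library calls (`stagewire.pipeline.run_pipeline`)
and as individual CLI verbs (`simulate`, `preprocess`, `diffnet`, `preserve`,
`score`, `survive`, `rewire`).

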