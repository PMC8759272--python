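# Methods

## Model and procedure

`stagewire` treats disease progression as a sequence of conditions
`normal → I → II → III → IV` and asks where the *co-expression structure*
(not the mean expression) changes.  The unit of analysis is the gene-gene
Pearson correlation within a condition's samples; the pipeline detects
modules whose correlation pattern in one stage departs from the pooled
remaining samples, scores them for disease relevance, and follows the
prognostic genes' edges across consecutive stages.

Assumptions worth stating explicitly:

* **Stage-vs-rest contrast.** Each stage's differential network contrasts
  that stage's samples against all other samples (normals included).  This
  is a design choice: it makes each contrast well-powered but means the
  "rest" pool dilutes, rather than excludes, signal from other stages.
* **Correlation, not causation.** All networks are undirected co-expression
  structures; "re-wiring" means a change in marginal correlation.
* **Proportional hazards.** The risk model assumes time-constant hazard
  ratios and uses Efron's approximation for tied event times.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `cpm_threshold` | 0.5 | genes with mean CPM below this are noise-level; mean-across-samples chosen as the aggregation (simple, monotone in expression) |
| CV filter | lowest quartile | keeps the `ceil(0.75 G)` most variable genes on the CPM scale; ties break by gene identifier |
| TMM trims | 30 % (M), 5 % (A) | standard double-trimming; reference sample = library whose upper quartile is closest to the mean upper quartile; factors normalized to geometric mean 1; output `log2(CPM_effective + 1)` |
| `connectivity_threshold` | 0.1 | applied to *scaled* connectivity `k_i/(G−1)` on the pooled correlation matrix, so the cutoff is invariant to gene-universe size; adjacency uses unsigned \|r\| so connectivity is a magnitude |
| `beta` | 6 | soft power of the differential dissimilarity; even so the signed-square difference is magnified without sign artifacts |
| `use_tom` | on | the topological-overlap transform pools evidence over shared differential neighbours before clustering |
| `merge_height` | 0.2 | clusters whose medoids are closer than this are one module |
| `min_module_size` | 10 | smaller clusters are `unassigned` |
| `n_perm` | 100 | permutation draws for preservation Z-scores and the non-randomness test |
| rewiring `cutoff` | 0.7 | edge presence is \|r\| ≥ 0.7 **inclusive**; unsigned, because negative associations are tracked with their sign and can participate in "reversed" calls |
| `vif_threshold` | 10 | iterated VIF pruning before the Cox fit |
| risk strata | Q1/Q3 | risk `< Q1` low, `> Q3` high (strict), else medium; identical scores all land in medium |

Numerical conventions: min–max rescaling of a constant vector yields 0.5
for every entry (keeps the stage-specificity score defined with one
module); the Fisher enrichment is one-sided (enrichment only), computed
over the coding genes of the post-preprocessing universe; the non-coding
score is 0 when a module has no non-coding genes; `−log₁₀` is used in the
enrichment score, though any base gives identical results after rescaling;
preservation classification assigns the boundary values Z = 2 and Z = 10 to
the "moderately stage-specific" class; top-module ties break by larger
module, then label order; module labels `module_k` are ordered by
decreasing size (a colour-name alias table is emitted for readability
only).

## Preservation statistics

The stage-specificity of a module is quantified by permutation Z-scores of
four statistics — two density (mean within-module correlation, mean
within-module unsigned adjacency, both measured in the test network) and
two connectivity (correlation of intramodular connectivity between
reference and test; correlation of the within-module correlation vectors).
`Z_density` and `Z_connectivity` are the medians of their pairs and
`Zsummary` their mean; `Medianrank` is the median over statistics of the
module's observed-value rank (1 = most preserved).  The reference
construction in the network-preservation literature uses twelve statistics;
keeping four representative ones is a deliberate reduction that preserves
the Zsummary construction at desk scale.  Permuted gene sets are drawn from
the clustered genes (widened to all genes when only one module exists, so
the null is non-degenerate); a statistic whose permutation spread is zero
(e.g. any reference-vs-test correlation when the two networks are
identical) contributes Z = 0.  The non-randomness p-value is
`(1 + #{permuted Zsummary ≤ observed}) / (n_perm + 1)` — the stage-specific
direction, with the add-one rule keeping p in (0, 1].

## The synthetic-data generator

The generator emulates a staged tumour cohort: the default configuration
uses 113 normals and 40/92/55/15 tumour samples for stages I–IV, 300 genes,
four planted 50-gene modules each co-expressed at peak correlation 0.85 in
every condition except its target stage (where the block decorrelates), and
exponential survival whose hazard doubles per standard deviation of the
stage-I module's mean expression with 20 % independent censoring.

Counts are log-normal–Poisson: a latent multivariate-normal log-expression
with the planted block correlations is exponentiated into relative
abundances, scaled by a per-sample library size drawn uniformly from
0.8–1.2 million, and Poisson-sampled.  Planted blocks are realised by a
one-factor model with per-gene loadings drawn once per module from
[0.8, 1] and shared across conditions: pairs correlate at `ρ·u_g·u_h`, so
modules carry a hub structure that persists wherever the module is
co-expressed — without it, within-module connectivity is exchangeable noise
and connectivity-based preservation statistics are uninformative.  Setting
`loading_range=(1, 1)` recovers exact equicorrelation for fixtures that
need all pairs at a stated correlation.  Re-wiring is planted only in the
correlation structure, never in the mean, so differential expression
carries no signal by construction.  One global seed drives expression,
annotations, and survival through a `SeedSequence` spawn tree (children 0,
1, 2 respectively); identical config + seed is bit-identical.

Annotations emulate a disease-gene list and non-coding catalogue: flag
counts are exact (`round(fraction × n)`), flags are seeded draws, disease
flags live on coding genes, nc-reported flags only on non-coding genes, and
the pipeline's default biases disease/nc-reported sampling toward planted
module genes (weight 5) so planted modules are disease-enriched ground
truth.  Censoring is an independent exponential clock calibrated so a
baseline patient is censored at the configured rate — censoring time is
independent of the event time given covariates, which keeps Cox estimates
unbiased.

What the generator does **not** emulate: batch effects, count
overdispersion beyond the latent log-normal (no gene-level dispersion
parameter), isoform structure, missing clinical data, correlated censoring,
or mean-expression stage trends (stage-trend classification is therefore
exercised by dedicated fixtures with constructed means, not by the default
pipeline run).  Passing tests show the pipeline recovers the signals it is
designed for under this model; they do not certify behaviour under real
TCGA-scale noise, confounding, or annotation error.

## Problem sizes and stability notes

The shipped experiments use 300-gene universes with 60 samples per
condition (module recovery), the default cohort sizes above (end-to-end
selection), n = 300 patients (hazard-ratio recovery), n = 40 patients
(log-rank versus a permutation oracle), and n = 100 samples per condition
(re-wiring calls) — sizes at which each recovery is sharp while a full test
run stays in the minutes range.

Stage IV carries only 15 samples in the default cohort, mirroring the rarity
of late-stage samples in real cohorts; its correlation estimates are noisy,
so stage-IV module boundaries are unstable (modules tend to merge) even
though the planted stage-IV genes still dominate the selected module.  The
asymptotic log-rank p differs from the exact permutation p by up to ~0.01
at n = 40 in the moderate-p regime; at the default effect size the
difference stays within the Monte-Carlo tolerance of a 10,000-draw oracle.

## Known limitations

* The two-group split per stage is stage-vs-rest; other groupings (e.g.
  stage-vs-normal) are not implemented.
* Four preservation statistics, not twelve; Zsummary magnitudes are
  therefore not numerically comparable to the reference implementation's.
* `detect_modules` is deterministic but its adaptive cut assumes the
  differential signal separates from the background in dendrogram height;
  extremely weak planted effects degrade to everything-unassigned rather
  than failing loudly.
* The Cox model is fitted and evaluated on the same cohort (apparent
  c-index), as in the workflow it reimplements; no cross-validation of the
  risk model is performed.
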