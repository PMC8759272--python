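"""Seeded multi-condition RNA-seq count simulator with planted co-expression re-wiring.

The generator emulates a staged tumour cohort (conditions ``normal, I, II,
III, IV``): blocks of genes share a latent correlation that differs by
condition (planted re-wiring), counts carry library-size variation for
normalisation to act on, annotations provide disease / non-coding flags for
enrichment scoring, and survival times depend on a known subset of genes so a
proportional-hazards fit has a recoverable effect size.

The count model is log-normal latent + Poisson sampling: per condition a
latent gene expression vector is drawn from a multivariate normal whose block
correlation follows the planted modules, exponentiated into relative
abundances, scaled by a per-sample library size, and Poisson-sampled.
Re-wiring is planted by changing the latent correlation per condition, never
the mean, so differential co-expression is detectable where differential
expression is not.

One global seed drives every sub-generator through a
``numpy.random.SeedSequence`` spawn tree: child 0 draws the expression and
libraries, child 1 the annotations, child 2 the survival times.  Identical
config + seed therefore yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("normal", "I", "II", "III", "IV")
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

__all__ = [
    "CONDITIONS",
    "STAGES",
    "ConfigurationError",
    "PlantedModule",
    "SurvivalEffectSpec",
    "SimulationConfig",
    "default_simulation_config",
    "generate_stage_dataset",
    "generate_annotations",
    "generate_survival",
    "generate_dataset_bundle",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedModule:
    """A block of genes with a common latent equicorrelation per condition.

    Parameters
    ----------
    gene_ids
        Gene identifiers belonging to the block; blocks must be disjoint.
    intra_correlation_by_condition
        Condition -> peak pairwise latent correlation in [-1, 1].  Conditions
        not listed default to 0 (independent).  Positive blocks are realised
        by a one-factor model with per-gene loadings in [0.8, 1], so pairs
        correlate at ``rho * u_g * u_h`` and modules carry hub structure;
        negative values are admitted only while the implied equicorrelation
        matrix stays positive definite.
    mean_log_expression
        Mean of the latent natural-log expression for the block's genes.
    """

    gene_ids: tuple[str, ...]
    intra_correlation_by_condition: Mapping[str, float]
    mean_log_expression: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(
            self,
            "intra_correlation_by_condition",
            dict(self.intra_correlation_by_condition),
        )
        for cond, rho in self.intra_correlation_by_condition.items():
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")
            if abs(rho) > 1:
                raise ConfigurationError(
                    f"intra correlation {rho} for condition {cond!r} outside [-1, 1]"
                )


@dataclass(frozen=True)
class SurvivalEffectSpec:
    """Exponential survival model whose log-hazard is linear in a gene signature.

    ``log hazard = log_hazard_per_unit * z`` where ``z`` is the standardized
    mean expression of ``risk_genes`` across patients; ``baseline_scale`` is
    the mean event time (days) at ``z = 0``; censoring is non-informative at
    the stated rate.
    """

    risk_genes: tuple[str, ...]
    log_hazard_per_unit: float = 0.0
    baseline_scale: float = 1500.0
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "risk_genes", tuple(self.risk_genes))
        if self.baseline_scale <= 0:
            raise ConfigurationError("baseline_scale must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.log_hazard_per_unit != 0 and not self.risk_genes:
            raise ConfigurationError("nonzero hazard effect requires risk_genes")


@dataclass
class SimulationConfig:
    n_genes: int
    n_samples_per_condition: dict[str, int]
    modules: list[PlantedModule]
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    noise_sd: float = 1.0
    survival: SurvivalEffectSpec | None = None
    annotation_fractions: dict[str, float] = field(
        default_factory=lambda: {"noncoding": 0.3, "disease": 0.2, "nc_reported": 0.15}
    )
    # weight multiplier applied to planted-module genes when sampling disease
    # and nc-reported flags; 1.0 means uniform annotation
    planted_disease_weight: float = 5.0
    # per-gene factor loadings are drawn uniformly from this range; (1, 1)
    # yields exact equicorrelation at the configured intra correlation
    loading_range: tuple[float, float] = (0.8, 1.0)
    seed: int = 0

    def validate(self) -> None:
        planted: set[str] = set()
        total = 0
        for mod in self.modules:
            ids = set(mod.gene_ids)
            if planted & ids:
                raise ConfigurationError(
                    f"planted gene sets overlap: {sorted(planted & ids)[:5]}"
                )
            planted |= ids
            total += len(ids)
        if self.n_genes < total:
            raise ConfigurationError(
                f"n_genes={self.n_genes} smaller than planted total {total}"
            )
        for cond in CONDITIONS:
            n = self.n_samples_per_condition.get(cond, 0)
            if n < 3:
                raise ConfigurationError(
                    f"condition {cond!r} has {n} samples; at least 3 required"
                )
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        lo_u, hi_u = self.loading_range
        if not (0 < lo_u <= hi_u <= 1):
            raise ConfigurationError("loading_range must satisfy 0 < lo <= hi <= 1")
        for key, frac in self.annotation_fractions.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"annotation fraction {key}={frac} outside [0, 1]")


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """Default study conditions: a staged ER-positive-like cohort.

    315 tumour samples split 40/92/55/15 across stages I-IV plus 113 normals;
    four planted 50-gene modules, each tightly co-expressed (r = 0.85)
    everywhere except its target stage, where the block decorrelates — i.e.
    each module is re-wired in exactly one stage.  100 unstructured background
    genes.  Survival hazard doubles per SD of the stage-I module signature.
    """
    sizes = {"normal": 113, "I": 40, "II": 92, "III": 55, "IV": 15}
    modules = []
    for k, stage in enumerate(STAGES, start=1):
        genes = tuple(f"M{k}_{i:03d}" for i in range(1, 51))
        rho = {cond: 0.85 for cond in CONDITIONS}
        rho[stage] = 0.0
        modules.append(
            PlantedModule(genes, rho, mean_log_expression=4.0)
        )
    survival = SurvivalEffectSpec(
        risk_genes=modules[0].gene_ids[:10],
        log_hazard_per_unit=float(np.log(2.0)),
        baseline_scale=1500.0,
        censoring_rate=0.2,
    )
    return SimulationConfig(
        n_genes=300,
        n_samples_per_condition=sizes,
        modules=modules,
        survival=survival,
        seed=seed,
    )


def _module_latent(
    rng: np.random.Generator, m: int, n: int, rho: float, loadings: np.ndarray
) -> np.ndarray:
    """Draw an m x n latent block with peak pairwise correlation rho.

    Positive blocks use a single-factor model with per-gene ``loadings`` in
    (0, 1], so gene pairs correlate at ``rho * u_g * u_h`` — the loading
    spread gives modules a realistic hub structure (shared across conditions
    because loadings are drawn once per module).  Negative rho falls back to
    an exact equicorrelation Cholesky draw.
    """
    if rho == 0:
        return rng.standard_normal((m, n))
    if rho > 0:
        lam = np.sqrt(rho) * loadings
        f = rng.standard_normal(n)
        e = rng.standard_normal((m, n))
        return lam[:, None] * f[None, :] + np.sqrt(1.0 - lam**2)[:, None] * e
    cov = np.full((m, m), rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            f"equicorrelation {rho} is not positive definite for block size {m}"
        ) from exc
    return chol @ rng.standard_normal((m, n))


def generate_stage_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PlantedModule]]:
    """Simulate a genes x samples count matrix with planted block re-wiring.

    Returns
    -------
    counts : DataFrame
        Nonnegative integer counts, genes in rows, samples in columns.
    design : DataFrame
        Indexed by sample, with a ``condition`` column.
    truth : list of PlantedModule
        The planted ground truth (copy of ``config.modules``).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    expr_seq, _, _ = root.spawn(3)
    rng = np.random.default_rng(expr_seq)

    planted_ids = [g for mod in config.modules for g in mod.gene_ids]
    n_bg = config.n_genes - len(planted_ids)
    bg_ids = [f"BG_{i:04d}" for i in range(1, n_bg + 1)]
    genes = planted_ids + bg_ids

    base_log = np.empty(config.n_genes)
    pos = 0
    for mod in config.modules:
        base_log[pos : pos + len(mod.gene_ids)] = mod.mean_log_expression
        pos += len(mod.gene_ids)
    base_log[pos:] = rng.normal(4.0, 1.0, size=n_bg)

    # per-module factor loadings, drawn once and shared across conditions so
    # the module's hub structure is preserved wherever its correlation is
    lo_u, hi_u = config.loading_range
    loadings = [
        rng.uniform(lo_u, hi_u, size=len(mod.gene_ids)) for mod in config.modules
    ]

    sample_ids: list[str] = []
    cond_labels: list[str] = []
    blocks: list[np.ndarray] = []
    for cond in CONDITIONS:
        n_c = config.n_samples_per_condition[cond]
        sample_ids += [f"{cond}_{i:03d}" for i in range(1, n_c + 1)]
        cond_labels += [cond] * n_c
        latent = np.empty((config.n_genes, n_c))
        pos = 0
        for mod, lam in zip(config.modules, loadings):
            m = len(mod.gene_ids)
            rho = mod.intra_correlation_by_condition.get(cond, 0.0)
            latent[pos : pos + m] = _module_latent(rng, m, n_c, rho, lam)
            pos += m
        latent[pos:] = rng.standard_normal((n_bg, n_c))
        blocks.append(latent)

    z = np.concatenate(blocks, axis=1)
    log_expr = base_log[:, None] + config.noise_sd * z
    rel = np.exp(log_expr)
    rel /= rel.sum(axis=0, keepdims=True)

    lo, hi = config.library_size_range
    libs = rng.integers(int(lo), int(hi) + 1, size=len(sample_ids))
    counts = rng.poisson(rel * libs[None, :])

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)
    design = pd.DataFrame({"condition": cond_labels}, index=pd.Index(sample_ids, name="sample"))
    return counts_df, design, list(config.modules)


def generate_annotations(
    gene_ids: Sequence[str],
    fractions: Mapping[str, float],
    seed: int,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assign coding / disease / nc-reported flags by seeded sampling.

    Flag counts are deterministic (``round(fraction * n_genes)``); which genes
    carry them is a seeded draw, optionally biased by per-gene ``weights``
    (e.g. to enrich planted modules for disease genes).  Disease flags are
    drawn among coding genes — mirroring a protein-coding disease-gene list —
    and nc-reported flags only among non-coding genes.
    """
    genes = list(gene_ids)
    n = len(genes)
    f_nc = float(fractions.get("noncoding", 0.0))
    f_dis = float(fractions.get("disease", 0.0))
    f_rep = float(fractions.get("nc_reported", 0.0))
    for name, f in (("noncoding", f_nc), ("disease", f_dis), ("nc_reported", f_rep)):
        if not 0 <= f <= 1:
            raise ConfigurationError(f"fraction {name}={f} outside [0, 1]")
    if f_rep > f_nc:
        raise ConfigurationError(
            f"nc_reported fraction {f_rep} exceeds noncoding fraction {f_nc}"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[1])
    w = np.ones(n) if weights is None else np.array([weights.get(g, 1.0) for g in genes], float)

    def draw(pool: np.ndarray, k: int) -> np.ndarray:
        if k == 0 or pool.size == 0:
            return np.empty(0, dtype=int)
        p = w[pool] / w[pool].sum()
        return rng.choice(pool, size=min(k, pool.size), replace=False, p=p)

    noncoding = np.zeros(n, bool)
    noncoding[draw(np.arange(n), round(f_nc * n))] = True
    disease = np.zeros(n, bool)
    disease[draw(np.flatnonzero(~noncoding), round(f_dis * n))] = True
    reported = np.zeros(n, bool)
    reported[draw(np.flatnonzero(noncoding), round(f_rep * n))] = True

    return pd.DataFrame(
        {
            "coding": ~noncoding,
            "disease_associated": disease,
            "nc_cancer_reported": reported,
        },
        index=pd.Index(genes, name="gene"),
    )


def generate_survival(
    expr: pd.DataFrame, spec: SurvivalEffectSpec, seed: int
) -> pd.DataFrame:
    """Draw exponential survival times whose hazard tracks a gene signature.

    ``expr`` is a normalized genes x samples matrix.  The linear predictor is
    the across-sample standardized mean expression of ``spec.risk_genes``;
    event times are exponential with mean ``baseline_scale / exp(lp)``.
    Censoring is an independent exponential clock calibrated so a baseline
    patient is censored with probability ``censoring_rate``.
    """
    if spec.log_hazard_per_unit != 0 and not spec.risk_genes:
        raise ConfigurationError("nonzero hazard effect requires risk_genes")
    missing = [g for g in spec.risk_genes if g not in expr.index]
    if missing:
        raise ConfigurationError(f"risk genes absent from expression matrix: {missing[:5]}")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    n = expr.shape[1]
    if spec.risk_genes:
        sig = expr.loc[list(spec.risk_genes)].mean(axis=0).to_numpy(float)
        sd = sig.std(ddof=0)
        z = (sig - sig.mean()) / sd if sd > 0 else np.zeros(n)
    else:
        z = np.zeros(n)
    lp = spec.log_hazard_per_unit * z
    event_t = rng.exponential(spec.baseline_scale * np.exp(-lp))
    if spec.censoring_rate > 0:
        # independent exponential censoring; its rate is set so that a
        # baseline (z = 0) patient is censored with the requested probability
        mu = spec.baseline_scale * (1.0 - spec.censoring_rate) / spec.censoring_rate
        censor_t = rng.exponential(mu, size=n)
    else:
        censor_t = np.full(n, np.inf)
    events = (event_t <= censor_t).astype(int)
    times = np.maximum(np.minimum(event_t, censor_t), 1e-8)
    return pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index(expr.columns, name="sample"),
    )


def generate_dataset_bundle(config: SimulationConfig) -> dict:
    """Simulate counts, design with survival, annotations, and ground truth.

    Convenience wrapper used by the pipeline and CLI: survival times are
    attached for tumour samples only (normals carry NA), and annotation
    sampling is biased toward planted-module genes by
    ``config.planted_disease_weight`` so planted modules are disease-enriched.
    """
    counts, design, truth = generate_stage_dataset(config)
    weights = {
        g: config.planted_disease_weight for mod in config.modules for g in mod.gene_ids
    }
    annotations = generate_annotations(
        counts.index, config.annotation_fractions, config.seed, weights=weights
    )
    design = design.copy()
    design["time"] = np.nan
    design["event"] = np.nan
    if config.survival is not None:
        tumour = design.index[design["condition"] != "normal"]
        log_cpm = np.log2(counts[tumour] / counts[tumour].sum(axis=0) * 1e6 + 1)
        surv = generate_survival(log_cpm, config.survival, config.seed)
        design.loc[tumour, "time"] = surv["time"]
        design.loc[tumour, "event"] = surv["event"]
    return {
        "counts": counts,
        "design": design,
        "annotations": annotations,
        "truth": truth,
        "config": config,
    }
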