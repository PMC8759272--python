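"""Permutation-based module preservation: Zsummary and Medianrank.

A module detected in a reference condition is *preserved* in a test
condition when its density (how strongly its genes inter-correlate) and its
connectivity pattern (which genes are the most connected within it) carry
over.  Each statistic is Z-scored against permuted gene sets of the same
size, so ``Zsummary`` measures how far the module sits above random;
``Medianrank`` ranks modules among each other by the observed statistics
(rank 1 = most preserved), which is robust to module size.

Low Zsummary and high Medianrank for a stage-vs-rest contrast mark a module
as stage-specific (re-wired in that stage).  The reference construction uses
twelve statistics; this implementation keeps four representative ones (two
density, two connectivity), a deliberate reduction that preserves the
Zsummary construction at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffnet import UNASSIGNED, CoexpressionNetwork

__all__ = [
    "PreservationResult",
    "preservation_stats",
    "classify_preservation",
    "nonrandomness_test",
]

_STATS = ("mean_cor", "mean_adj", "cor_kim", "cor_cor")


@dataclass
class PreservationResult:
    """Per-module preservation table plus the permutation ensemble."""

    table: pd.DataFrame  # index module; Zsummary, Medianrank, Z_density, Z_connectivity
    observed: pd.DataFrame  # per-module observed statistics
    perm_zsummary: dict[str, np.ndarray] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int = 0


def _module_stats(
    idx: np.ndarray, ref: np.ndarray, test: np.ndarray
) -> tuple[float, float, float, float]:
    """Density and connectivity statistics for one gene set.

    mean_cor / mean_adj are measured in the test network; cor_kim and cor_cor
    compare the intramodular connectivity pattern and the correlation vectors
    between reference and test.
    """
    rt = test[np.ix_(idx, idx)]
    rr = ref[np.ix_(idx, idx)]
    m = idx.size
    off = ~np.eye(m, dtype=bool)
    mean_cor = float(rt[off].mean())
    mean_adj = float(np.abs(rt[off]).mean())

    kim_r = np.abs(rr).sum(axis=1) - 1.0
    kim_t = np.abs(rt).sum(axis=1) - 1.0
    cor_kim = _safe_cor(kim_r, kim_t)
    iu = np.triu_indices(m, k=1)
    cor_cor = _safe_cor(rr[iu], rt[iu])
    return mean_cor, mean_adj, cor_kim, cor_cor


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _zscore(obs: float, perm: np.ndarray) -> float:
    sd = perm.std(ddof=1) if perm.size > 1 else 0.0
    if sd == 0:
        return 0.0
    return float((obs - perm.mean()) / sd)


def preservation_stats(
    partition: pd.Series,
    refNet: CoexpressionNetwork,
    testNet: CoexpressionNetwork,
    n_perm: int = 100,
    seed: int = 0,
) -> PreservationResult:
    """Zsummary / Medianrank preservation of each module between two networks.

    For every module of ``partition`` (ignoring ``unassigned``), four observed
    statistics are computed and Z-scored against ``n_perm`` seeded draws of
    same-size gene sets from the clustered genes.  ``Z_density`` and
    ``Z_connectivity`` are the medians of their statistic pairs and
    ``Zsummary`` their mean; ``Medianrank`` is the median over statistics of
    the module's observed-value rank (1 = most preserved).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    genes = list(refNet.genes)
    if (refNet.genes != testNet.genes).any():
        raise ValueError("reference and test networks must share gene order")
    pos = {g: i for i, g in enumerate(genes)}
    missing = [g for g in partition.index if g not in pos]
    if missing:
        raise ValueError(f"partition genes absent from networks: {missing[:5]}")

    modules: dict[str, np.ndarray] = {}
    for label in partition.unique():
        if label == UNASSIGNED:
            continue
        idx = np.array([pos[g] for g in partition.index[partition == label]])
        if idx.size < 3:
            warnings.warn(f"module {label!r} has fewer than 3 genes; skipped")
            continue
        modules[label] = idx
    if not modules:
        raise ValueError("no module with at least 3 genes")

    clustered = np.concatenate(list(modules.values()))
    max_size = max(v.size for v in modules.values())
    pool = clustered if clustered.size > max_size else np.arange(len(genes))

    ref, test = refNet.adjacency, testNet.adjacency
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(genes)]))

    obs = pd.DataFrame(
        {lab: _module_stats(idx, ref, test) for lab, idx in modules.items()},
        index=list(_STATS),
    ).T
    labels = sorted(modules, key=lambda m: (-(partition == m).sum(), m))

    z_rows, perm_zsum = {}, {}
    for lab in labels:
        idx = modules[lab]
        perms = np.empty((n_perm, len(_STATS)))
        for k in range(n_perm):
            draw = rng.choice(pool, size=idx.size, replace=False)
            perms[k] = _module_stats(draw, ref, test)
        z = [_zscore(obs.loc[lab, s], perms[:, i]) for i, s in enumerate(_STATS)]
        z_density = float(np.median(z[:2]))
        z_conn = float(np.median(z[2:]))
        z_rows[lab] = {
            "Z_density": z_density,
            "Z_connectivity": z_conn,
            "Zsummary": (z_density + z_conn) / 2.0,
        }
        # Zsummary of each permuted set against the same ensemble, for the
        # non-randomness test
        mu, sd = perms.mean(axis=0), perms.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        zp = (perms - mu) / sd
        perm_zsum[lab] = (np.median(zp[:, :2], axis=1) + np.median(zp[:, 2:], axis=1)) / 2.0

    table = pd.DataFrame(z_rows).T
    # rank 1 = most preserved = largest observed statistic
    ranks = obs.loc[table.index].rank(ascending=False, method="average")
    table["Medianrank"] = ranks.median(axis=1)
    result = PreservationResult(
        table=table[["Zsummary", "Medianrank", "Z_density", "Z_connectivity"]],
        observed=obs.loc[table.index],
        perm_zsummary=perm_zsum,
        n_permutations=n_perm,
        seed=seed,
    )
    return result


def classify_preservation(z: float) -> str:
    """Preservation class from Zsummary: < 2 stage-specific, 2..10 moderate, > 10 not."""
    if z < 2:
        return "stage-specific"
    if z <= 10:
        return "moderately stage-specific"
    return "not stage-specific"


def nonrandomness_test(
    partition: pd.Series,
    refNet: CoexpressionNetwork,
    testNet: CoexpressionNetwork,
    observed: PreservationResult,
    n_perm: int = 100,
    seed: int = 1,
) -> pd.Series:
    """Empirical p-value that a module's low Zsummary is non-random.

    ``p = (1 + #{permuted Zsummary <= observed Zsummary}) / (n_perm + 1)`` —
    the stage-specific direction, so small p means the module is less
    preserved than almost every random gene set.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20 for the non-randomness test")
    ensemble = observed
    if observed.n_permutations < n_perm or observed.seed != seed:
        ensemble = preservation_stats(partition, refNet, testNet, n_perm=n_perm, seed=seed)
    out = {}
    for lab, zperm in ensemble.perm_zsummary.items():
        z_obs = ensemble.table.loc[lab, "Zsummary"]
        out[lab] = (1.0 + np.sum(zperm[:n_perm] <= z_obs)) / (n_perm + 1.0)
    return pd.Series(out, name="p_perm")
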