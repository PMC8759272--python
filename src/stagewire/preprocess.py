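"""Count-matrix cleaning, filtering, and TMM normalization.

The filter chain is fixed: remove NA/all-zero genes, drop genes with mean
CPM below 0.5, drop the least-variable quartile by coefficient of variation,
TMM-normalize to log2(CPM + 1), and finally drop weakly connected genes on
the pooled correlation network.  Gene count is non-increasing through the
chain; the sample set never changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "clean_genes",
    "cpm_filter",
    "cv_filter",
    "tmm_factors",
    "tmm_normalize",
    "connectivity",
    "connectivity_filter",
    "preprocess_counts",
]


def clean_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with any missing value or with all-zero counts."""
    keep = counts.notna().all(axis=1) & (counts.fillna(0) != 0).any(axis=1)
    out = counts.loc[keep]
    if out.empty:
        raise ValueError("all genes removed: no gene has complete, nonzero counts")
    return out


def _cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    libs = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"nonpositive library size for samples: {bad[:5]}")
    return counts / libs * 1e6


def cpm_filter(counts: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Drop genes whose mean counts-per-million across samples is < threshold."""
    mean_cpm = _cpm(counts).mean(axis=1)
    return counts.loc[mean_cpm >= threshold]


def cv_filter(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop the least-variable quartile of genes by coefficient of variation.

    CV = sd/mean on the CPM scale; ``ceil(0.75 * G)`` genes are retained.
    Ties are broken by ascending gene identifier so the cut is deterministic.
    """
    if counts.shape[0] < 4:
        raise ValueError("cv_filter requires at least 4 genes")
    cpm = _cpm(counts)
    mean = cpm.mean(axis=1)
    if (mean == 0).any():
        bad = mean.index[mean == 0].tolist()
        raise ValueError(f"zero-mean genes must be removed first: {bad[:5]}")
    cv = cpm.std(axis=1, ddof=1) / mean
    n_keep = int(np.ceil(0.75 * counts.shape[0]))
    order = pd.DataFrame({"cv": cv.to_numpy(), "ident": list(cv.index)}).sort_values(
        ["cv", "ident"], ascending=[False, True]
    )
    keep = set(order["ident"].iloc[:n_keep])
    return counts.loc[[g in keep for g in counts.index]]


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (one per sample).

    The reference sample is the library whose upper quartile of scaled counts
    is closest to the mean upper quartile.  For each sample, log-ratios (M)
    and mean log-abundances (A) against the reference are computed over genes
    expressed in both; genes in the extreme 30% of M or 5% of A are trimmed,
    and the factor is the precision-weighted mean of the surviving M values.
    Factors are normalized to geometric mean 1.
    """
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad[:5]}")
    scaled = counts.div(libs, axis=1)
    uq = scaled.apply(lambda c: float(np.quantile(c, 0.75)))
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(float)
    nref = libs[ref_sample]

    factors = {}
    for s in counts.columns:
        obs = counts[s].to_numpy(float)
        if s == ref_sample:
            factors[s] = 1.0
            continue
        ns = libs[s]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            factors[s] = 1.0
            continue
        po, pr = obs[ok] / ns, ref[ok] / nref
        m = np.log2(po / pr)
        if np.max(np.abs(m)) < 1e-6:  # identical composition: nothing to trim
            factors[s] = 1.0
            continue
        a = 0.5 * np.log2(po * pr)
        w = (ns - obs[ok]) / (ns * obs[ok]) + (nref - ref[ok]) / (nref * ref[ok])
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = pd.Series(m).rank(method="first").to_numpy()
        rank_a = pd.Series(a).rank(method="first").to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
            continue
        f = (w[keep] * m[keep]).sum() / w[keep].sum()
        factors[s] = float(2.0 ** f)

    fac = pd.Series(factors).reindex(counts.columns)
    fac /= np.exp(np.log(fac).mean())  # geometric mean 1
    return fac


def tmm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """TMM-normalized expression: log2(CPM + 1) on effective library sizes."""
    factors = tmm_factors(counts)
    eff_libs = counts.sum(axis=0) * factors
    cpm = counts / eff_libs * 1e6
    return np.log2(cpm + 1.0)


def connectivity(adjacency: pd.DataFrame, gene: str | None = None):
    """Scaled connectivity k_i = sum_{j != i} |r_ij| / (G - 1), in [0, 1].

    ``adjacency`` is a symmetric gene x gene correlation matrix.  With
    ``gene`` given, returns that gene's scalar connectivity; otherwise a
    Series over all genes.
    """
    a = adjacency.abs()
    g = a.shape[0]
    if g < 2:
        raise ValueError("connectivity needs at least 2 genes")
    k = (a.sum(axis=1) - np.diag(a.to_numpy())) / (g - 1)
    if gene is None:
        return k
    if gene not in k.index:
        raise KeyError(f"gene {gene!r} absent from adjacency")
    return float(k[gene])


def connectivity_filter(expr: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Drop genes whose scaled connectivity on the pooled correlation is < threshold."""
    if expr.shape[0] < 3:
        raise ValueError("connectivity_filter requires at least 3 genes")
    corr = pd.DataFrame(
        np.corrcoef(expr.to_numpy(float)), index=expr.index, columns=expr.index
    )
    k = connectivity(corr)
    return expr.loc[k >= threshold]


def preprocess_counts(
    counts: pd.DataFrame,
    cpm_threshold: float = 0.5,
    connectivity_threshold: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full chain clean -> CPM -> CV -> TMM -> connectivity.

    Returns the normalized expression matrix and a per-step removal report.
    """
    report: dict[str, int] = {"input_genes": int(counts.shape[0])}
    step = clean_genes(counts)
    report["removed_clean"] = int(counts.shape[0] - step.shape[0])
    prev = step.shape[0]
    step = cpm_filter(step, cpm_threshold)
    report["removed_cpm"] = int(prev - step.shape[0])
    prev = step.shape[0]
    step = cv_filter(step)
    report["removed_cv"] = int(prev - step.shape[0])
    expr = tmm_normalize(step)
    prev = expr.shape[0]
    expr = connectivity_filter(expr, connectivity_threshold)
    report["removed_connectivity"] = int(prev - expr.shape[0])
    report["output_genes"] = int(expr.shape[0])
    return expr, report
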