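"""Composite disease-and-stage-specificity scoring of modules.

Each module of a stage receives

* ``SS`` in [0, 2] — stage-specificity: ``(1 - rescale(Zsummary)) +
  rescale(Medianrank)`` across the stage's modules, so the least preserved
  module scores highest;
* ``BCR`` in [0, 1] — disease relation: min-max rescaled ``-log10 p`` of a
  one-sided Fisher's exact enrichment of disease-associated coding genes;
* ``BCRNCR`` in [0, 1] — non-coding disease relation: the fraction of the
  module's non-coding genes already reported in the disease;

and the composite ``BCSS = SS + BCR + BCRNCR`` in [0, 4].  The module with
the maximal composite is selected as the stage's disease-related,
stage-specific subnetwork.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .preservation import PreservationResult

__all__ = [
    "rescale",
    "ss_score",
    "bcr_pvalue",
    "bcr_score",
    "bcrncr_score",
    "bcss_score",
    "score_modules",
    "select_top_module",
]


def rescale(values: pd.Series | np.ndarray) -> pd.Series:
    """Min-max rescale onto [0, 1]; a constant vector maps to 0.5 everywhere."""
    v = pd.Series(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return pd.Series(0.5, index=v.index)
    return (v - lo) / (hi - lo)


def ss_score(results: PreservationResult) -> pd.Series:
    """Stage-specificity score per module: (1 - rescale(Zsummary)) + rescale(Medianrank)."""
    t = results.table
    if t.empty:
        raise ValueError("no modules to score")
    return (1.0 - rescale(t["Zsummary"])) + rescale(t["Medianrank"])


def bcr_pvalue(
    module_genes: Iterable[str], annotation: pd.DataFrame, universe: Iterable[str]
) -> float:
    """One-sided Fisher's exact enrichment p of disease genes among coding module genes.

    The 2x2 table crosses module membership with disease association over the
    coding genes of the universe.
    """
    universe = set(universe)
    module = set(module_genes)
    if not universe:
        raise ValueError("empty universe")
    if not module <= universe:
        raise ValueError("module genes must lie within the universe")
    ann = annotation.loc[annotation.index.intersection(list(universe))]
    coding = set(ann.index[ann["coding"]])
    disease = set(ann.index[ann["coding"] & ann["disease_associated"]])
    mod_coding = module & coding
    a = len(mod_coding & disease)
    b = len(mod_coding) - a
    c = len(disease) - a
    d = len(coding) - len(mod_coding) - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def bcr_score(
    module_gene_sets: Mapping[str, set],
    annotation: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Disease-relation score per module of one stage.

    Returns a DataFrame with ``fisher_p`` and the min-max rescaled
    ``-log10 p`` as ``bcr`` (the log base cancels in the rescale).
    """
    universe = set(universe)
    p = pd.Series(
        {lab: bcr_pvalue(genes, annotation, universe) for lab, genes in module_gene_sets.items()}
    )
    return pd.DataFrame({"fisher_p": p, "bcr": rescale(-np.log10(p))})


def bcrncr_score(module_genes: Iterable[str], annotation: pd.DataFrame) -> float:
    """Fraction of the module's non-coding genes reported in the disease (0 if none)."""
    genes = annotation.index.intersection(list(module_genes))
    ann = annotation.loc[genes]
    nc = ann.index[~ann["coding"]]
    if len(nc) == 0:
        return 0.0
    return float(ann.loc[nc, "nc_cancer_reported"].sum() / len(nc))


def bcss_score(ss: float, bcr: float, bcrncr: float) -> float:
    """Composite score SS + BCR + BCRNCR, bounded in [0, 4]."""
    if not 0 <= ss <= 2:
        raise ValueError(f"ss={ss} outside [0, 2]")
    if not 0 <= bcr <= 1:
        raise ValueError(f"bcr={bcr} outside [0, 1]")
    if not 0 <= bcrncr <= 1:
        raise ValueError(f"bcrncr={bcrncr} outside [0, 1]")
    return float(ss + bcr + bcrncr)


def score_modules(
    partition: pd.Series,
    preservation: PreservationResult,
    annotation: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score every module of a stage and flag the selected one.

    Returns a DataFrame indexed by module with columns
    ``size, ss, bcr, bcrncr, bcss, fisher_p, selected``.
    """
    labels = list(preservation.table.index)
    gene_sets = {lab: set(partition.index[partition == lab]) for lab in labels}
    uni = set(partition.index) if universe is None else set(universe)
    ss = ss_score(preservation)
    bcr = bcr_score(gene_sets, annotation, uni)
    rows = {}
    for lab in labels:
        ncr = bcrncr_score(gene_sets[lab], annotation)
        rows[lab] = {
            "size": len(gene_sets[lab]),
            "ss": float(ss[lab]),
            "bcr": float(bcr.loc[lab, "bcr"]),
            "bcrncr": ncr,
            "fisher_p": float(bcr.loc[lab, "fisher_p"]),
        }
        rows[lab]["bcss"] = bcss_score(rows[lab]["ss"], rows[lab]["bcr"], ncr)
    out = pd.DataFrame(rows).T
    out["size"] = out["size"].astype(int)
    out["selected"] = False
    out.loc[select_top_module(out), "selected"] = True
    return out


def select_top_module(scores: pd.DataFrame) -> str:
    """Module with maximal BCSS; ties broken by larger module, then label order."""
    if scores.empty:
        raise ValueError("no modules to select from")
    ranked = scores.sort_values(
        ["bcss", "size"], ascending=[False, False], kind="mergesort"
    )
    top_bcss, top_size = ranked.iloc[0][["bcss", "size"]]
    tied = ranked[(ranked["bcss"] == top_bcss) & (ranked["size"] == top_size)]
    return sorted(tied.index)[0]
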