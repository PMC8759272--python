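"""Thresholded per-condition networks and gain/loss/reversed edge classification.

Over a prognostic gene set, a co-expression network per condition keeps only
strong edges (|r| >= cutoff, default 0.7).  Between consecutive conditions
(normal -> I -> II -> III -> IV) an edge is a *gain* if it appears only in
the later condition, a *loss* if it disappears, and *reversed* if it is
strong in both with opposite signs.  Genes incident to many changed edges
are re-wiring hubs; combined with prognosis, trend, novelty, and re-wiring
breadth they rank progression biomarkers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CONDITIONS

__all__ = [
    "TRANSITIONS",
    "ThresholdedNetwork",
    "RewiringEdgeSet",
    "condition_network",
    "classify_rewiring",
    "hub_nodes",
    "rank_progression_biomarkers",
]

TRANSITIONS: tuple[tuple[str, str], ...] = tuple(zip(CONDITIONS[:-1], CONDITIONS[1:]))


@dataclass
class ThresholdedNetwork:
    condition: str
    genes: pd.Index
    corr: pd.DataFrame  # full signed correlation over the gene set
    cutoff: float

    @property
    def edges(self) -> dict[frozenset, float]:
        """Unordered strong pairs -> signed correlation."""
        r = self.corr.to_numpy()
        out = {}
        for i, j in zip(*np.where(np.triu(np.abs(r) >= self.cutoff, k=1))):
            out[frozenset((self.genes[i], self.genes[j]))] = float(r[i, j])
        return out


@dataclass
class RewiringEdgeSet:
    transition: tuple[str, str]
    edges: pd.DataFrame  # gene_a, gene_b, class, r_earlier, r_later
    cutoff: float
    hubs: list[str] = field(default_factory=list)


def condition_network(
    expr: pd.DataFrame,
    samples,
    genes,
    condition: str = "",
    cutoff: float = 0.7,
) -> ThresholdedNetwork:
    """Signed Pearson network over one condition's samples, keeping |r| >= cutoff."""
    samples = list(samples)
    genes = [g for g in genes if g in expr.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = expr.loc[genes, samples]
    sd = sub.std(axis=1, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        warnings.warn(f"zero-variance genes excluded: {dropped[:5]}")
        sub = sub.loc[sd > 0]
    r = np.corrcoef(sub.to_numpy(float))
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(np.clip(r, -1, 1), index=sub.index, columns=sub.index)
    return ThresholdedNetwork(condition=condition, genes=sub.index, corr=corr, cutoff=cutoff)


def classify_rewiring(
    earlier: ThresholdedNetwork, later: ThresholdedNetwork
) -> RewiringEdgeSet:
    """Classify edge changes between two conditions.

    gain: strong only later; loss: strong only earlier; reversed: strong in
    both with opposite signs.  Unchanged edges are omitted, so comparing a
    network with itself yields the empty set.
    """
    if earlier.cutoff != later.cutoff:
        raise ValueError("networks were thresholded at different cutoffs")
    shared = earlier.genes.intersection(later.genes)
    re_ = earlier.corr.loc[shared, shared].to_numpy()
    rl = later.corr.loc[shared, shared].to_numpy()
    cut = earlier.cutoff
    pe, pl = np.abs(re_) >= cut, np.abs(rl) >= cut
    rows = []
    iu = np.triu_indices(len(shared), k=1)
    for i, j in zip(*iu):
        a, b = shared[i], shared[j]
        if pe[i, j] and not pl[i, j]:
            klass = "loss"
        elif pl[i, j] and not pe[i, j]:
            klass = "gain"
        elif pe[i, j] and pl[i, j] and np.sign(re_[i, j]) != np.sign(rl[i, j]):
            klass = "reversed"
        else:
            continue
        ga, gb = sorted((a, b))
        rows.append((ga, gb, klass, float(re_[i, j]), float(rl[i, j])))
    edges = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "class", "r_earlier", "r_later"]
    )
    out = RewiringEdgeSet(
        transition=(earlier.condition, later.condition), edges=edges, cutoff=cut
    )
    if not edges.empty:
        out.hubs = hub_nodes(out)
    return out


def hub_nodes(changes: RewiringEdgeSet, top_fraction: float = 0.1) -> list[str]:
    """Genes with the most changed incident edges.

    Hubs are the top ``ceil(top_fraction * n)`` of the ``n`` genes that have
    at least one changed edge (minimum one hub); ties break by identifier.
    """
    if changes.edges.empty:
        raise ValueError("no changed edges")
    degree = (
        pd.concat([changes.edges["gene_a"], changes.edges["gene_b"]])
        .value_counts()
        .sort_index()
        .sort_values(ascending=False, kind="mergesort")
    )
    k = max(1, math.ceil(top_fraction * len(degree)))
    return degree.index[:k].tolist()


def rank_progression_biomarkers(indices: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by five progression indices.

    ``indices`` has one row per gene with boolean columns ``prognostic``,
    ``trend`` (ascending or descending), ``hub``, ``novel``, ``rewired`` and
    an integer ``n_rewired_transitions``.  Genes are ordered by the number of
    satisfied indices, ties by re-wiring breadth, then identifier.
    """
    required = ["prognostic", "trend", "hub", "novel", "rewired"]
    missing = [c for c in required + ["n_rewired_transitions"] if c not in indices.columns]
    if missing:
        raise ValueError(f"missing index columns: {missing}")
    out = indices.copy()
    out["n_indices"] = out[required].astype(bool).sum(axis=1)
    out = (
        out.assign(_gene=out.index.astype(str))
        .sort_values(
            ["n_indices", "n_rewired_transitions", "_gene"],
            ascending=[False, False, True],
        )
        .drop(columns="_gene")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
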