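"""Per-condition correlation networks, differential dissimilarity, and module extraction.

A differential co-expression network contrasts the Pearson correlation
structure of one sample group against another: gene pairs whose signed
squared correlation changes strongly between groups get a high differential
dissimilarity.  Hierarchical clustering of that dissimilarity (optionally
passed through a topological-overlap transform, which smooths pairwise
changes by shared neighbourhoods) yields re-wired gene modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionNetwork",
    "DiffMatrix",
    "correlation_network",
    "differential_dissimilarity",
    "detect_modules",
    "stage_differential",
    "color_alias_table",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

# presentation-only aliases for module labels, for readability of reports
_COLOR_NAMES = (
    "FloralWhite", "Orange", "Plum2", "IndianRed4", "YellowGreen", "Bisque4",
    "LightGreen", "Salmon", "MediumOrchid", "LightPink3", "LightSteelBlue1",
    "SkyBlue", "DarkSeaGreen", "Thistle", "Goldenrod", "SlateGray",
)


@dataclass
class CoexpressionNetwork:
    """Symmetric signed Pearson adjacency for one sample group."""

    genes: pd.Index
    adjacency: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.genes, columns=self.genes)


@dataclass
class DiffMatrix:
    """Symmetric differential dissimilarity in [0, 1] between two conditions."""

    genes: pd.Index
    dissimilarity: np.ndarray
    beta: int
    conditions: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dissimilarity, index=self.genes, columns=self.genes)


def correlation_network(expr: pd.DataFrame, samples=None) -> CoexpressionNetwork:
    """Pairwise Pearson correlation over a sample subset."""
    sub = expr if samples is None else expr[list(samples)]
    if sub.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {sub.shape[1]}")
    x = sub.to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = sub.index[sd == 0].tolist()
        raise ValueError(f"zero-variance genes in subset: {bad[:5]}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CoexpressionNetwork(genes=sub.index, adjacency=r, n_samples=sub.shape[1])


def _tom_dissimilarity(d: np.ndarray) -> np.ndarray:
    """1 - topological overlap of a nonnegative adjacency with zero diagonal."""
    a = d.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    out = 1.0 - tom
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, 1.0)


def differential_dissimilarity(
    netA: CoexpressionNetwork,
    netB: CoexpressionNetwork,
    beta: int = 6,
    use_tom: bool = True,
) -> DiffMatrix:
    """Differential dissimilarity d_ij = (|sign(cA) cA^2 - sign(cB) cB^2| / 2)^(beta/2).

    The signed square preserves the direction of each correlation while the
    soft power ``beta`` (even, default 6) suppresses small fluctuations.  With
    ``use_tom`` the matrix is passed through a topological-overlap transform
    and 1 - TOM is returned, so genes sharing differential neighbours cluster
    together.  Identical networks yield the all-zero dissimilarity.
    """
    if beta <= 0 or beta % 2:
        raise ValueError("beta must be a positive even integer")
    if len(netA.genes) != len(netB.genes) or (netA.genes != netB.genes).any():
        raise ValueError("networks must share the same genes in the same order")
    ca, cb = netA.adjacency, netB.adjacency
    d = (np.abs(np.sign(ca) * ca**2 - np.sign(cb) * cb**2) / 2.0) ** (beta / 2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    if use_tom and d.max() > 0:
        d = _tom_dissimilarity(d)
    return DiffMatrix(
        genes=netA.genes,
        dissimilarity=np.clip(d, 0.0, 1.0),
        beta=beta,
        conditions=("A", "B"),
    )


def _medoid(d: np.ndarray, members: np.ndarray) -> int:
    sub = d[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def detect_modules(
    diff: DiffMatrix,
    merge_height: float = 0.2,
    min_module_size: int = 10,
    cut_fraction: float = 0.99,
) -> pd.Series:
    """Extract re-wired modules by hybrid hierarchical clustering.

    Average-linkage clustering of the dissimilarity is cut adaptively the
    way a dynamic tree cut does: at ``q05 + cut_fraction * (h_max - q05)``,
    where ``q05`` and ``h_max`` are the 5th percentile and maximum of the
    dendrogram join heights — robust to the compressed height scale a
    topological-overlap dissimilarity produces.  Clusters below
    ``min_module_size`` become ``unassigned``; a PAM-like pass reassigns each
    clustered gene to its nearest cluster medoid; clusters whose medoids are
    closer than ``merge_height`` are merged.  Labels ``module_1, module_2,
    ...`` are ordered by decreasing size.

    Returns a Series mapping gene -> label.
    """
    d = np.asarray(diff.dissimilarity, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    genes = diff.genes
    n = d.shape[0]
    if n < 2 * min_module_size:
        raise ValueError("too few genes for module detection")
    if d.max() == 0:
        return pd.Series(UNASSIGNED, index=genes, name="module")

    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    q05 = float(np.quantile(heights, 0.05))
    cut = q05 + cut_fraction * (heights.max() - q05)
    labels = fcluster(z, t=cut, criterion="distance")

    # size filter
    sizes = pd.Series(labels).value_counts()
    keep = set(sizes.index[sizes >= min_module_size])
    assigned = np.array([lab if lab in keep else 0 for lab in labels])

    if (assigned > 0).any():
        # PAM-like step: reassign clustered genes to the nearest medoid
        clusters = sorted(set(assigned) - {0})
        medoids = {c: _medoid(d, np.flatnonzero(assigned == c)) for c in clusters}
        med_idx = np.array([medoids[c] for c in clusters])
        for i in np.flatnonzero(assigned > 0):
            assigned[i] = clusters[int(np.argmin(d[i, med_idx]))]

        # merge clusters whose medoids sit below the merge height
        clusters = sorted(set(assigned[assigned > 0]))
        medoids = {c: _medoid(d, np.flatnonzero(assigned == c)) for c in clusters}
        parent = {c: c for c in clusters}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for i, ci in enumerate(clusters):
            for cj in clusters[i + 1 :]:
                if d[medoids[ci], medoids[cj]] < merge_height:
                    parent[find(cj)] = find(ci)
        assigned = np.array([find(c) if c > 0 else 0 for c in assigned])

        # drop merged clusters that fell below the size threshold
        sizes = pd.Series(assigned[assigned > 0]).value_counts()
        small = set(sizes.index[sizes < min_module_size])
        assigned = np.array([0 if c in small else c for c in assigned])

    out = pd.Series(UNASSIGNED, index=genes, name="module")
    sizes = pd.Series(assigned[assigned > 0]).value_counts()
    # order by size descending, ties by smallest member gene id for determinism
    order = sorted(
        sizes.index,
        key=lambda c: (-sizes[c], min(genes[assigned == c])),
    )
    for rank, c in enumerate(order, start=1):
        out.iloc[assigned == c] = f"module_{rank}"
    return out


def stage_differential(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    beta: int = 6,
    use_tom: bool = True,
) -> tuple[DiffMatrix, CoexpressionNetwork, CoexpressionNetwork]:
    """Stage-vs-rest differential dissimilarity for one stage.

    Returns (diff, stage_network, rest_network); the rest network pools every
    other condition, including normals.
    """
    in_stage = design.index[design["condition"] == stage]
    rest = design.index[design["condition"] != stage]
    if len(in_stage) < 3 or len(rest) < 3:
        raise ValueError(f"stage {stage!r} split leaves fewer than 3 samples per group")
    net_stage = correlation_network(expr, in_stage)
    net_rest = correlation_network(expr, rest)
    diff = differential_dissimilarity(net_stage, net_rest, beta=beta, use_tom=use_tom)
    diff.conditions = (stage, "rest")
    return diff, net_stage, net_rest


def color_alias_table(partition: pd.Series) -> dict[str, str]:
    """Readable colour aliases for module labels (presentation only)."""
    mods = sorted(
        {m for m in partition.unique() if m != UNASSIGNED},
        key=lambda m: int(m.split("_")[1]),
    )
    return {
        m: _COLOR_NAMES[i % len(_COLOR_NAMES)] + ("" if i < len(_COLOR_NAMES) else str(i))
        for i, m in enumerate(mods)
    }
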