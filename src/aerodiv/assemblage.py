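"""Temporal-assemblage clustering of genera and cluster-level series.

Genera whose log-ratios are nearly constant over time behave proportionally
and belong to one temporal assemblage.  The pairwise log-ratio variation
matrix is therefore used as a dissimilarity for agglomerative clustering
(Ward by default, treating the variation entries as squared distances), cut
at a fixed number of groups.  Cluster-level weekly shares and per-cluster
calendar-week seasonal profiles summarize the solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .compositional import CompositionMatrix, LogRatioMatrix

__all__ = ["ClusterSolution", "cluster_genera", "aggregate_clusters", "seasonal_profile"]


@dataclass
class ClusterSolution:
    """Genus -> cluster assignment plus the dendrogram that produced it."""

    assignments: pd.Series  # genus -> cluster id (1..k)
    linkage: np.ndarray  # scipy linkage matrix (merges + heights)
    k: int
    distance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = np.sort(self.assignments.unique())
        if not np.array_equal(ids, np.arange(1, self.k + 1)):
            raise ValueError("cluster ids must be 1..k with every id used")

    def members(self, cluster_id: int) -> list:
        return list(self.assignments.index[self.assignments == cluster_id])

    def to_newick(self) -> str:
        """Dendrogram as a Newick-like nested string with merge heights."""
        labels = list(self.assignments.index)
        n = len(labels)
        nodes = {i: labels[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + i] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def cluster_genera(
    vm: pd.DataFrame, k: int = 17, linkage: str = "ward"
) -> ClusterSolution:
    """Agglomerative clustering of the variation matrix cut at k groups.

    The variation matrix var(ln x_i/x_j) is treated as a squared
    dissimilarity (its square root enters the linkage), matching Ward's
    geometry; ``average`` and ``complete`` are available alternatives.
    Cluster ids are relabeled 1..k by order of first appearance in the input
    genus order, so the labeling is deterministic and order-independent up
    to genus permutation of the input.
    """
    genera = vm.index
    if k > len(genera):
        raise ValueError("k may not exceed the number of genera")
    m = vm.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-10) or not np.allclose(np.diag(m), 0):
        raise ValueError("variation matrix must be symmetric with zero diagonal")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError("linkage must be ward, average or complete")
    d = squareform(np.sqrt(np.maximum(m, 0.0)), checks=False)
    Z = hierarchy.linkage(d, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel by first appearance for deterministic ids
    order = {}
    relabeled = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in order:
            order[c] = len(order) + 1
        relabeled[i] = order[c]
    return ClusterSolution(
        assignments=pd.Series(relabeled, index=genera, name="cluster"),
        linkage=Z,
        k=int(relabeled.max()),
        distance=vm,
    )


def aggregate_clusters(
    solution: ClusterSolution, comp: CompositionMatrix
) -> pd.DataFrame:
    """Cluster x week relative abundances: sum of member shares per week.

    Weekly cluster shares close to 1 because the members partition the
    composition.
    """
    assign = solution.assignments.reindex(comp.genera)
    if assign.isna().any():
        raise ValueError("cluster solution does not cover all genera")
    return comp.proportions.groupby(assign).sum()


def seasonal_profile(
    solution: ClusterSolution,
    lr: LogRatioMatrix,
    calendar_week: pd.Series,
    week_range: tuple[int, int] = (21, 41),
) -> pd.DataFrame:
    """Cluster x calendar-week median of member log-ratio abundances.

    For CLR input (weeks x genera coordinates) the median is taken across
    member genera and across years for each calendar week in the range.
    """
    lo, hi = week_range
    if lo > hi:
        raise ValueError("empty calendar week range")
    cw = calendar_week.reindex(lr.coords.index)
    keep = (cw >= lo) & (cw <= hi)
    if not keep.any():
        raise ValueError("no weeks fall in the requested calendar range")
    coords = lr.coords.loc[keep.to_numpy()]
    cw = cw[keep]

    # genus-resolved matrix required (CLR); columns are genera
    if lr.kind != "clr":
        raise ValueError("seasonal profiles need genus-resolved (CLR) coordinates")
    out = {}
    for cid in range(1, solution.k + 1):
        members = solution.members(cid)
        sub = coords[members]
        # pooled median over member genera and years per calendar week
        out[cid] = sub.groupby(cw.to_numpy()).apply(
            lambda df: float(np.median(df.to_numpy()))
        )
    prof = pd.DataFrame(out).T
    prof.index.name = "cluster"
    prof.columns.name = "calendar_week"
    return prof
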