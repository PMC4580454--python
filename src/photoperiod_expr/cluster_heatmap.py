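"""Relative-expression normalization and Ward clustering of gene profiles.

Each selected gene's FPKM profile is converted to a relative expression
level: the profile mean is subtracted and the result divided by the sample
standard deviation (denominator T-1, the convention of R's ``sd``).  Rows
with zero variance carry no temporal signal and are excluded rather than
transformed.  For display, relative levels are clipped to [-3, +3]; the
clipped matrix is used only for rendering, never for clustering or
enrichment (for T = 7 the largest attainable |z| under sample sd is
sqrt(6)*sqrt(6/7) ~ 2.27, so the clip is in fact vacuous there).

Clustering is agglomerative with the Ward criterion on Euclidean row
distances.  Two variants of "Ward" are in circulation, mirroring R's
``hclust`` methods:

* ``d2`` (default): the Lance-Williams recurrence applied to squared
  Euclidean distances, merge heights on the distance scale (R ``ward.D2``,
  the textbook minimum-variance method);
* ``d``: the same coefficients applied to the unsquared distances
  (R ``ward.D``).

Both are computed through :func:`scipy.cluster.hierarchy.linkage`; the
``d`` variant feeds the recurrence square-rooted distances and reports
squared merge heights, which reproduces ``ward.D`` merges and heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_tables import ExpressionMatrix, TimeCourseDesign

__all__ = [
    "RelativeMatrix",
    "ClusterResult",
    "zscore_rows",
    "clip_for_display",
    "ward_cluster",
    "group_profiles",
]


@dataclass
class RelativeMatrix:
    """Row-normalized (mean 0, sample sd 1) expression profiles."""

    gene_ids: List[str]
    values: np.ndarray  # (G, T), dimensionless z-units
    design: TimeCourseDesign

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.design.labels,
        )


@dataclass
class ClusterResult:
    """A K-group cut of a Ward dendrogram over clustered genes.

    ``group_of`` maps each gene to a label in 1..K, with labels assigned in
    order of first appearance along ``leaf_order`` so Group 1..K reads
    top-to-bottom on the heatmap.  ``merge_history`` is the linkage matrix:
    rows (node_i, node_j, height, size) in merge order.
    """

    group_of: Dict[str, int]
    merge_history: np.ndarray  # scipy linkage matrix, shape (G-1, 4)
    leaf_order: List[str]
    K: int


def zscore_rows(matrix: ExpressionMatrix) -> Tuple[RelativeMatrix, List[str]]:
    """Normalize each row to mean 0 / sample sd 1; exclude flat rows.

    Returns the relative matrix over retained genes and the list of
    excluded (zero-variance) gene_ids.
    """
    if len(matrix.design) < 2:
        raise ValueError("normalization requires >= 2 time points")
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    excluded = [g for g, f in zip(matrix.gene_ids, flat) if f]
    keep = ~flat
    with np.errstate(invalid="ignore"):
        z = (matrix.values - mean) / sd
    rel = RelativeMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        values=z[keep],
        design=matrix.design,
    )
    return rel, excluded


def clip_for_display(relmatrix: RelativeMatrix, bound: float = 3.0) -> np.ndarray:
    """Clip relative levels to [-bound, +bound] for heatmap rendering only."""
    if bound <= 0:
        raise ValueError("clip bound must be positive")
    return np.clip(relmatrix.values, -bound, bound)


def ward_linkage(values: np.ndarray, variant: str = "d2") -> np.ndarray:
    """Linkage matrix for Ward clustering of rows (see module docstring)."""
    if variant == "d2":
        return hierarchy.linkage(values, method="ward")
    if variant == "d":
        d = pdist(values, metric="euclidean")
        Z = hierarchy.linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2  # back to the ward.D height scale
        return Z
    raise ValueError(f"unknown ward variant {variant!r} (expected 'd2' or 'd')")


def ward_cluster(
    relmatrix: RelativeMatrix, K: int, variant: str = "d2"
) -> ClusterResult:
    """Cut the Ward tree into K groups.

    Group labels 1..K follow first appearance along the dendrogram leaf
    order.  Deterministic for a given input order.
    """
    G = len(relmatrix.gene_ids)
    if not 1 <= K <= G:
        raise ValueError(f"K must be in 1..{G}, got {K}")
    Z = ward_linkage(relmatrix.values, variant=variant)
    raw = hierarchy.fcluster(Z, t=K, criterion="maxclust")
    if len(np.unique(raw)) != K:
        # maxclust can under-shoot when merge heights tie; cut by explicit
        # merge count instead (the first G-K merges define the K groups)
        raw = hierarchy.fcluster(Z, t=Z[G - K - 1, 2] if K < G else 0,
                                 criterion="distance")
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [relmatrix.gene_ids[i] for i in leaves]
    relabel: Dict[int, int] = {}
    for i in leaves:
        relabel.setdefault(int(raw[i]), len(relabel) + 1)
    group_of = {
        g: relabel[int(raw[i])] for i, g in enumerate(relmatrix.gene_ids)
    }
    return ClusterResult(
        group_of=group_of, merge_history=Z, leaf_order=leaf_order, K=K
    )


def group_profiles(
    relmatrix: RelativeMatrix, clusters: ClusterResult
) -> pd.DataFrame:
    """Per-group arithmetic-mean relative profile at each time point."""
    df = relmatrix.to_frame()
    missing = set(df.index) - set(clusters.group_of)
    if missing:
        raise ValueError(f"clusters do not cover genes: {sorted(missing)[:5]}")
    groups = pd.Series({g: clusters.group_of[g] for g in df.index}, name="group")
    out = df.groupby(groups).mean()
    out.index.name = "group"
    return out
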