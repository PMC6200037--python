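"""Pan/core genome accounting and gene-content clustering.

From a presence/absence matrix the module computes pan- and core-genome
sizes, the matrix of accessory gene families shared between strain
pairs, and a Euclidean-distance dendrogram over the shared-count rows
(average linkage), whose two-group cut exposes the panel's
subpopulation structure in gene content.

"Accessory" means not present in 100% of strains; the fraction is a
parameter. Rows fed to the Euclidean distance include the diagonal
(per-strain accessory count) — the self-count is as much a part of a
strain's gene-content profile as its sharing pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .clustering import PresenceAbsenceMatrix


def pan_core_sizes(matrix: PresenceAbsenceMatrix,
                   core_fraction: float = 1.0) -> tuple[int, int]:
    """(pan, core): families with >= 1 carrier, and families present in
    at least ``core_fraction`` of strains (default: all of them)."""
    col = matrix.values.sum(axis=0)
    pan = int((col >= 1).sum())
    core = int((col >= core_fraction * len(matrix.strains)).sum())
    return pan, core


@dataclass
class SharedCountMatrix:
    """Symmetric strains x strains counts of shared accessory families.

    The diagonal holds each strain's own accessory family count.
    """

    strains: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.strains),) * 2:
            raise ValueError("counts shape does not match strain list")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("shared-count matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strains, columns=self.strains)


def shared_counts(matrix: PresenceAbsenceMatrix,
                  accessory_only: bool = True,
                  core_fraction: float = 1.0) -> SharedCountMatrix:
    """Counts of gene families shared by each strain pair.

    With ``accessory_only`` (default), families present in
    >= ``core_fraction`` of strains are dropped first, since core
    families are shared by every pair and carry no grouping signal.
    """
    vals = matrix.values
    if accessory_only:
        col = vals.sum(axis=0)
        vals = vals[:, col < core_fraction * len(matrix.strains)]
    counts = vals.astype(int) @ vals.astype(int).T
    return SharedCountMatrix(list(matrix.strains), counts)


@dataclass
class Dendrogram:
    """Average-linkage dendrogram over strains (scipy linkage encoding)."""

    strains: list[str]  # leaf order fed to linkage (sorted)
    linkage: np.ndarray

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def euclidean_dendrogram(shared: SharedCountMatrix,
                         method: str = "average") -> Dendrogram:
    """Agglomerative dendrogram on Euclidean distances of shared-count rows.

    The distance between strains i and j is the Euclidean norm of
    (row_i - row_j) of the shared-count matrix. Strains are sorted
    lexicographically before linkage so equal-distance merges resolve to
    the smallest label pair.
    """
    if len(shared.strains) < 2:
        raise ValueError("dendrogram needs at least two strains")
    order = np.argsort(shared.strains)
    strains = [shared.strains[i] for i in order]
    rows = shared.counts[np.ix_(order, order)].astype(float)
    cond = pdist(rows, metric="euclidean")
    Z = hierarchy.linkage(cond, method=method)
    return Dendrogram(strains=strains, linkage=Z)


def cut_groups(dendro: Dendrogram, k: int = 2) -> dict[str, int]:
    """Cut the dendrogram at the height giving exactly ``k`` clusters.

    Returns strain -> cluster label (1-based, relabeled so that cluster 1
    contains the lexicographically smallest strain).
    """
    n = len(dendro.strains)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    labels = hierarchy.fcluster(dendro.linkage, t=k, criterion="maxclust")
    if len(set(labels)) != k:
        raise ValueError(f"tie in merge heights prevents an exact {k}-cluster cut")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for strain, lab in zip(dendro.strains, labels):
        remap.setdefault(int(lab), len(remap) + 1)
        out[strain] = remap[int(lab)]
    return out


def dendrogram_to_newick(dendro: Dendrogram) -> str:
    """Serialize with merge heights as node heights (branch length =
    parent height - child height)."""
    tree = hierarchy.to_tree(dendro.linkage)

    def rec(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{dendro.strains[node.id]}:{parent_height:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
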