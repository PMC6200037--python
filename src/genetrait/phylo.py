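"""Core-genome and gene-cluster phylogenies.

The pipeline builds distance trees: single-copy core CDSs are
concatenated per strain, pairwise Jukes-Cantor distances are computed,
and a neighbor-joining tree is estimated, with bootstrap support from
column resampling. Synthetic homologs are gap-free and equal-length, so
no alignment step is needed; real inputs must arrive pre-aligned.

The neighbor-joining implementation is canonical (Q-criterion with the
Studier-Keppler distance update) with deterministic tie-breaking on the
taxon-label pair, so identical inputs always give identical trees.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch, the usual convention for distance trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .clustering import GeneFamily
from .io_formats import Alignment


# ---------------------------------------------------------------------------
# Core-genome concatenation


def concat_core_alignment(families: Sequence[GeneFamily],
                          strains: Sequence[str],
                          sequences: Mapping[str, str]) -> Alignment:
    """Concatenate single-copy core family CDSs into one alignment.

    Keeps only families present in 100% of ``strains`` with exactly one
    member per strain; concatenates their sequences in family-id order.
    Raises if members of a kept family differ in length (unaligned input).
    """
    strains = list(strains)
    kept = []
    for fam in sorted(families, key=lambda f: f.family_id):
        if set(fam.members) != set(strains) or not fam.is_single_copy:
            continue
        seqs = {s: sequences[fam.members[s][0]] for s in strains}
        if len({len(v) for v in seqs.values()}) != 1:
            raise ValueError(
                f"family {fam.family_id}: members differ in length; "
                "input must be aligned")
        kept.append(seqs)
    if not kept:
        raise ValueError("no single-copy core families found")
    rows = ["".join(seqs[s] for seqs in kept) for s in strains]
    return Alignment(names=strains, rows=rows)


# ---------------------------------------------------------------------------
# Jukes-Cantor distances

_JC_SATURATION = 0.75


def _encode(aln: Alignment) -> np.ndarray:
    mat = np.frombuffer("".join(aln.rows).encode(), dtype="S1")
    return mat.reshape(len(aln.rows), aln.length)


def _jc_from_p(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances, d = -(3/4) ln(1 - (4/3) p).

    Sites with a non-ACGT symbol in either row are excluded pairwise.
    Raises for a saturated pair (observed difference fraction >= 0.75).
    """
    mat = _encode(aln)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype="S1"))
    n = len(aln.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable sites between {aln.names[i]} and {aln.names[j]}")
            p = float((mat[i][both] != mat[j][both]).mean())
            if p >= _JC_SATURATION:
                raise ValueError(
                    f"saturated pair {aln.names[i]}/{aln.names[j]} (p={p:.3f})")
            d[i, j] = d[j, i] = _jc_from_p(p)
    return DistanceMatrix(d, ids=list(aln.names))


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Canonical algorithm: at each step join the pair minimizing
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); ties broken by
    the sorted label pair. Branch lengths from the standard formulas;
    the Studier-Keppler update defines distances to the new node.
    Negative branch lengths are clamped to zero and the deficit moved to
    the sibling branch. The returned tree is unrooted, represented with
    a trifurcating root.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    # sort key per active node: its smallest descendant label
    keys: list[str] = list(labels)

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _q, _pk, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)],
                       new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(_pk)]

    # final three nodes: closed-form three-point branch lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    root = TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.length = max(ln, 0.0)
        root.append(node)
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    """Clamp a negative estimate to 0, moving the deficit to its sibling."""
    if x < 0:
        y = max(y + x, 0.0)
        x = 0.0
    if y < 0:
        x = max(x + y, 0.0)
        y = 0.0
    return x, y


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap support


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an unrooted tree.

    Each internal edge is encoded as the frozenset of leaf names on the
    side *not* containing the lexicographically smallest leaf, so the
    encoding is rooting-invariant.
    """
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        parts.add(side)
    return parts


@dataclass
class BootstrapResult:
    tree: TreeNode  # point-estimate tree with integer supports on node.name
    supports: dict[frozenset, int]  # bipartition -> percent
    n_reps: int
    skipped: int  # replicates dropped for JC saturation
    informative: int = 0  # internal edges of positive length in the point tree


def bootstrap_support(aln: Alignment, n_reps: int = 1000,
                      seed: int | None = None) -> BootstrapResult:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate is run through JC distances and neighbor joining, and the
    support of an internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same bipartition.
    Replicates in which some pair saturates are skipped and counted.
    Identical columns are collapsed to site patterns with multiplicities,
    which makes resampling a multinomial draw over patterns and leaves
    all distances unchanged.
    """
    rng = np.random.default_rng(seed)
    point_tree = nj_tree(jc_distance(aln))
    target = bipartitions(point_tree)
    counts = {bp: 0 for bp in target}

    mat = _encode(aln)
    n, L = mat.shape
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    valid = np.isin(patterns, np.frombuffer(b"ACGT", dtype="S1"))
    # per-pattern pairwise difference / validity indicators
    npat = patterns.shape[1]
    diff = np.zeros((n, n, npat), dtype=np.float64)
    vboth = np.zeros((n, n, npat), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            diff[i, j] = diff[j, i] = both & (patterns[i] != patterns[j])
            vboth[i, j] = vboth[j, i] = both

    skipped = 0
    done = 0
    labels = list(aln.names)
    while done + skipped < n_reps:
        w = rng.multinomial(L, weights / weights.sum()).astype(float)
        nd = diff @ w
        nv = vboth @ w
        np.fill_diagonal(nv, 1.0)
        if np.any(nv == 0):
            skipped += 1
            continue
        p = nd / nv
        np.fill_diagonal(p, 0.0)
        if np.any(p >= _JC_SATURATION):
            skipped += 1
            continue
        dmat = -0.75 * np.log1p(-4.0 * p / 3.0)
        rep_tree = nj_tree(DistanceMatrix((dmat + dmat.T) / 2, ids=labels))
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
        done += 1

    supports = {bp: (round(100 * c / done) if done else 0)
                for bp, c in counts.items()}
    for node in point_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        leaves = {t.name for t in point_tree.tips()}
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if min(leaves) in side:
            side = frozenset(leaves - side)
        node.name = str(supports.get(side, 0))
    informative = sum(1 for node in point_tree.non_tips(include_self=False)
                      if (node.length or 0.0) > 0.0)
    return BootstrapResult(tree=point_tree, supports=supports,
                           n_reps=n_reps, skipped=skipped,
                           informative=informative)
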