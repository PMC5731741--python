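"""Adaptive dendrogram cutting with a minimum-cluster-size guarantee.

A single fixed-height cut of an agglomerative tree either fuses distinct
tight clusters or shatters them into fragments; adaptive ("dynamic") tree
cutting instead starts from the branches below a height cap and recursively
decomposes each branch wherever the joining merge sits well above the
internal cohesion of the two sub-branches.  The contract implemented here:

* every assigned cluster has at least ``min_module_size`` leaves; leaves in
  branches too small to form a cluster get label 0 (unassigned);
* no merge above ``max_tree_height`` ever joins two clusters;
* ``deep_split`` controls how aggressively branches are decomposed into
  sub-clusters;
* the partition depends only on the tree, never on leaf input order.

Branch decomposition uses a height-gap rule.  Within a branch, the sorted
internal merge heights of a homogeneous cluster rise smoothly, while a
branch containing several genuine sub-clusters shows a wide empty band
between the within-cluster merges and the few high merges that join the
sub-clusters.  The branch is cut inside the highest such band whose width,
relative to the root height of the enclosing top-level branch (so that
minute height differences deep inside an already tight cluster never count
as structure), reaches a gap threshold (0.15 when ``deep_split`` is on,
0.35 when off) and whose cut produces at least one
component of ``min_module_size`` or more leaves; cutting inside one band
separates any number of sub-clusters at once, and each component is then
decomposed recursively.  Components too small to stand as clusters are
left unassigned — outliers merging high above a tight cluster are shaved
off rather than absorbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = ["Dendrogram", "TreeCutParams", "hierarchical_tree", "dynamic_tree_cut"]

_GAP_DEEP = 0.15
_GAP_SHALLOW = 0.35


@dataclass(frozen=True)
class TreeCutParams:
    max_tree_height: float = 1.0
    deep_split: bool = True
    min_module_size: int = 50

    def __post_init__(self) -> None:
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative tree: a SciPy linkage matrix plus leaf labels."""

    Z: np.ndarray
    leaf_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix does not match leaf count")
        heights = self.Z[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


def hierarchical_tree(
    dissimilarity: np.ndarray,
    labels: list[str] | tuple[str, ...],
    method: str = "average",
) -> Dendrogram:
    """Agglomerative tree of a square dissimilarity matrix.

    ``method`` is any SciPy linkage method; average linkage (UPGMA) is the
    default used throughout the pipeline.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("dissimilarity must be square and match labels")
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method=method)
    return Dendrogram(Z, tuple(labels))


def dynamic_tree_cut(d: Dendrogram, p: TreeCutParams) -> np.ndarray:
    """Cut a dendrogram into clusters of at least ``min_module_size`` leaves.

    Returns an integer label per leaf, in leaf order; 0 marks unassigned
    leaves.  Clusters are numbered 1.. in decreasing size (ties broken by
    their smallest leaf index), so relabelling is deterministic.
    """
    n = d.n_leaves
    labels = np.zeros(n, dtype=int)
    if p.min_module_size > n:
        warnings.warn(
            f"min_module_size={p.min_module_size} exceeds item count {n}; "
            "all items left unassigned",
            stacklevel=2,
        )
        return labels

    Z = d.Z
    n_nodes = 2 * n - 1

    height = np.zeros(n_nodes)
    left = np.full(n_nodes, -1, dtype=int)
    right = np.full(n_nodes, -1, dtype=int)
    count = np.ones(n_nodes, dtype=int)
    for t in range(n - 1):
        node = n + t
        left[node] = int(Z[t, 0])
        right[node] = int(Z[t, 1])
        height[node] = Z[t, 2]
        count[node] = count[left[node]] + count[right[node]]

    root = n_nodes - 1

    # branches below the height cap, found top-down
    static_branches: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if height[node] <= p.max_tree_height + 1e-12:
            static_branches.append(node)
        else:
            stack.extend((left[node], right[node]))

    gap_min = _GAP_DEEP if p.deep_split else _GAP_SHALLOW

    def internal_heights(branch: int) -> np.ndarray:
        hs: list[float] = []
        stack = [branch]
        while stack:
            x = stack.pop()
            if x >= n:
                hs.append(height[x])
                stack.extend((left[x], right[x]))
        return np.sort(np.asarray(hs))

    def components_below(branch: int, h_cut: float) -> list[int]:
        """Maximal subtrees of ``branch`` whose root merge is <= h_cut."""
        comps: list[int] = []
        stack = [branch]
        while stack:
            x = stack.pop()
            if height[x] <= h_cut:
                comps.append(x)
            else:
                stack.extend((left[x], right[x]))
        return comps

    def decompose(branch: int) -> list[int]:
        """Recursively cut a branch inside its widest admissible height band."""
        out: list[int] = []
        scale = float(height[branch]) if branch >= n else 0.0
        work = [branch]
        while work:
            node = work.pop()
            if node < n or count[node] < 2 * p.min_module_size or scale <= 0:
                out.append(node)
                continue
            hs = internal_heights(node)
            gaps = np.diff(hs)
            # candidate bands from highest to lowest; take the first that both
            # clears the gap threshold and yields >= 2 viable components
            candidates = [
                i for i in np.argsort(gaps)[::-1]
                if gaps[i] / scale >= gap_min
            ]
            candidates.sort(reverse=True)
            done = True
            for i in candidates:
                h_cut = (hs[i] + hs[i + 1]) / 2.0
                comps = components_below(node, h_cut)
                if sum(count[x] >= p.min_module_size for x in comps) >= 1:
                    work.extend(comps)
                    done = False
                    break
            if done:
                out.append(node)
        return out

    clusters: list[list[int]] = []
    for branch in static_branches:
        if count[branch] < p.min_module_size:
            continue
        for node in decompose(branch):
            if count[node] < p.min_module_size:
                continue  # fragment produced by a cut: left unassigned
            leaves: list[int] = []
            stack = [node]
            while stack:
                x = stack.pop()
                if x < n:
                    leaves.append(x)
                else:
                    stack.extend((left[x], right[x]))
            clusters.append(sorted(leaves))

    clusters.sort(key=lambda ls: (-len(ls), ls[0]))
    for cid, leaves in enumerate(clusters, start=1):
        labels[leaves] = cid
    return labels
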