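"""Hybrid dynamic dendrogram cutting.

Adaptive alternative to a fixed-height cut: branches of a hierarchical
clustering are accepted as clusters where they are *distinct* — tight
inside relative to the height at which they attach to the rest of the tree
— and split top-down as long as both sides stay distinct. Small offshoots
are left unassigned by the tree stage and then reattached to the nearest
cluster by average distance (PAM-like stage), so every leaf ends up
labeled.

Two tuning knobs follow the conventions of dynamic tree cutting as used in
gene-network analysis:

``min_cluster_size``
    smallest branch accepted as its own cluster;
``deep_split`` (0..4)
    sensitivity to nested substructure; the number of clusters is
    non-decreasing in ``deep_split``.

Distinctness of a branch attaching at height ``h``:

    size >= min_cluster_size  and  (h - core_scatter) / h_max >= min_gap

where ``core_scatter`` is the mean of the branch's lowest merge heights
(its first ``min_cluster_size`` leaves to agglomerate), ``h_max`` the tree
height, and ``min_gap`` shrinks with ``deep_split`` (0.27, 0.2025, 0.135,
0.0675, 0.0375 — three quarters of one minus the usual core-scatter
presets). At high sensitivity the cut can report clusters in unstructured
data; the randomized-table silhouette validation downstream is the
intended guard against that.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform

_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)
MIN_GAP = tuple((1.0 - mcs) * 3.0 / 4.0 for mcs in _MAX_CORE_SCATTER)


def _as_square(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim == 1:
        return squareform(dist)
    return dist


def cut_tree_hybrid(
    linkage: np.ndarray,
    dist: np.ndarray,
    min_cluster_size: int = 10,
    deep_split: int = 2,
) -> np.ndarray:
    """Cut a SciPy linkage into clusters; labels 1..k over the leaves.

    All leaves are assigned (the PAM stage reattaches tree-stage orphans to
    the cluster at minimal average distance). Degenerate trees — all merge
    heights zero, or too few leaves to support a split — yield a single
    cluster. Cluster numbering is deterministic: decreasing size, ties by
    smallest leaf index.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    linkage = np.asarray(linkage, dtype=float)
    n = linkage.shape[0] + 1
    if n == 1:
        return np.array([1])
    square = _as_square(dist)
    h_max = linkage[-1, 2]
    if h_max <= 0:
        return np.ones(n, dtype=int)
    min_gap = MIN_GAP[deep_split]

    heights = np.zeros(2 * n - 1)
    heights[n:] = linkage[:, 2]
    children = {n + i: (int(linkage[i, 0]), int(linkage[i, 1])) for i in range(n - 1)}

    sizes = np.ones(2 * n - 1, dtype=int)
    # sorted merge heights per subtree, kept truncated to the core size
    core_heights: dict[int, np.ndarray] = {i: np.empty(0) for i in range(n)}
    for i in range(n - 1):
        left, right = children[n + i]
        sizes[n + i] = sizes[left] + sizes[right]
        merged = np.concatenate(
            (core_heights[left], core_heights[right], [linkage[i, 2]])
        )
        merged.sort()
        core_heights[n + i] = merged[: max(min_cluster_size, 2)]

    def leaves(node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            if cur < n:
                out.append(cur)
            else:
                stack.extend(children[cur])
        return out

    def core_scatter(node: int) -> float:
        if node < n:
            return 0.0
        core = core_heights[node][: max(min(min_cluster_size, sizes[node]) - 1, 1)]
        return float(core.mean())

    def distinct(node: int, attach: float) -> bool:
        if sizes[node] < min_cluster_size:
            return False
        return (attach - core_scatter(node)) / h_max >= min_gap

    clusters: list[list[int]] = []
    unassigned: list[int] = []

    def recurse(node: int) -> None:
        if node < n:
            unassigned.append(node)
            return
        left, right = children[node]
        attach = heights[node]
        dl, dr = distinct(left, attach), distinct(right, attach)
        if dl and dr:
            recurse(left)
            recurse(right)
        elif dl and sizes[right] < min_cluster_size:
            recurse(left)
            unassigned.extend(leaves(right))
        elif dr and sizes[left] < min_cluster_size:
            recurse(right)
            unassigned.extend(leaves(left))
        else:
            clusters.append(leaves(node))

    recurse(2 * n - 2)

    if not clusters:
        return np.ones(n, dtype=int)

    clusters.sort(key=lambda mem: (-len(mem), min(mem)))
    labels = np.zeros(n, dtype=int)
    for idx, member in enumerate(clusters, start=1):
        labels[member] = idx

    for leaf in sorted(unassigned):
        mean_d = [square[leaf, member].mean() for member in clusters]
        labels[leaf] = int(np.argmin(mean_d)) + 1
    return labels


def flat_cut(linkage: np.ndarray, k: int) -> np.ndarray:
    """Plain flat cut into exactly k clusters (used by k-reduction)."""
    return fcluster(np.asarray(linkage, dtype=float), t=k, criterion="maxclust")
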