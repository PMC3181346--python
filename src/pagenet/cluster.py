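"""Agglomerative hierarchical clustering of samples.

Distance is 1 - Pearson correlation over log2 intensities; linkage is
unweighted average (UPGMA). The agglomeration is implemented here rather
than delegated so that the merge order under tied distances is exactly
specified: among pairs at the minimum distance, the pair whose
(min leaf ID, max leaf ID) is lexicographically smallest merges first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PagenetError
from .expression import ExpressionMatrix


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    item_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.item_ids), len(self.item_ids)):
            raise ValueError("distance matrix shape does not match item count")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        self.d = (d + d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)


@dataclass
class Dendrogram:
    """Merge tree over ``leaf_ids``.

    ``merges`` lists n-1 tuples (left, right, height) in merge order, using
    scipy-style node indexing: leaves are 0..n-1, the t-th merge creates
    node n+t. Heights are non-decreasing (average linkage is reducible).
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves needs exactly n-1 merges")
        prev = -np.inf
        for _, _, h in self.merges:
            if h < prev - 1e-9:
                raise PagenetError("merge heights are not non-decreasing")
            prev = max(prev, h)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def correlation_distance(matrix: ExpressionMatrix) -> DistanceMatrix:
    """1 - Pearson r between samples, over log2 values of all retained genes."""
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes for correlation distance")
    log2 = matrix.log2().to_numpy()
    sd = log2.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise PagenetError(f"zero-variance sample: {matrix.sample_ids[zero[0]]!r}")
    r = np.corrcoef(log2, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(matrix.sample_ids, d)


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with a deterministic lexicographic tie-break.

    Inter-cluster distance is the mean over all cross-pairs of the input
    distances, maintained with the Lance-Williams size-weighted update.
    """
    ids = dist.item_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # active cluster state keyed by node index
    size = {i: 1 for i in range(n)}
    rep = {i: ids[i] for i in range(n)}  # lexicographically smallest leaf ID
    dmat: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[frozenset((i, j))] = float(dist.d[i, j])

    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    for t in range(n - 1):
        best = None
        for key, val in dmat.items():
            i, j = sorted(key)
            pair_ids = (min(rep[i], rep[j]), max(rep[i], rep[j]))
            cand = (val, pair_ids, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        height, _, i, j = best
        new = n + t
        merges.append((i, j, height))
        for k in active - {i, j}:
            dik = dmat.pop(frozenset((i, k)))
            djk = dmat.pop(frozenset((j, k)))
            dmat[frozenset((new, k))] = (size[i] * dik + size[j] * djk) / (
                size[i] + size[j]
            )
        del dmat[frozenset((i, j))]
        size[new] = size[i] + size[j]
        rep[new] = min(rep[i], rep[j])
        active -= {i, j}
        active.add(new)
    return Dendrogram(ids, merges)


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths derived from ultrametric heights.

    A node merged at height h sits at ultrametric height h/2; each branch
    length is the parent's ultrametric height minus the child's.
    """
    n = dendrogram.n_leaves
    uh = {i: 0.0 for i in range(n)}
    label = {i: dendrogram.leaf_ids[i] for i in range(n)}
    children = {}
    for t, (left, right, h) in enumerate(dendrogram.merges):
        node = n + t
        uh[node] = h / 2.0
        children[node] = (left, right)

    def render(node: int, parent_uh: float) -> str:
        length = parent_uh - uh[node]
        if node < n:
            return f"{label[node]}:{length}"
        left, right = children[node]
        return f"({render(left, uh[node])},{render(right, uh[node])}):{length}"

    root = n + len(dendrogram.merges) - 1
    if root < n:  # unreachable: dendrogram always has >= 1 merge
        return f"{label[root]};"
    left, right = children[root]
    return f"({render(left, uh[root])},{render(right, uh[root])});"


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into k clusters by undoing the last k-1 merges.

    Returns leaf ID -> cluster label; clusters are numbered 0.. in order of
    their lexicographically smallest member.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (left, right, _) in enumerate(dendrogram.merges[: n - k]):
        node = n + t
        parent[find(left)] = node
        parent[find(right)] = node

    groups: dict[int, list[str]] = {}
    for i, leaf in enumerate(dendrogram.leaf_ids):
        groups.setdefault(find(i), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda leaves: min(leaves))
    return {leaf: c for c, leaves in enumerate(ordered) for leaf in leaves}


def write_clusters(assignment: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcluster\n")
        for leaf, c in assignment.items():
            fh.write(f"{leaf}\t{c}\n")
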