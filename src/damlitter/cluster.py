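"""Complete-linkage agglomerative clustering and Newick export.

Implemented as the textbook O(n^3) agglomeration: start from singleton
clusters, repeatedly merge the pair of clusters with the smallest
inter-cluster distance, where the distance between two clusters is the
*maximum* pairwise distance between their members (complete linkage).
Ties are broken by the lexicographically smallest pair of cluster creation
indices, which makes runs bit-reproducible. Family dendrograms are small
(a dam plus a litter over four time points), so the cubic algorithm is the
clear, dependable choice.

Node numbering follows the usual linkage convention: leaves are 0..n-1 in
input order, the i-th merge creates node n+i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .records import ValidationError

_NEWICK_UNSAFE = set(" \t\n()[]':;,")


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float


@dataclass
class LinkageTree:
    """Result of a complete-linkage agglomeration.

    ``leaves`` are the sample labels in input order; ``merges`` lists the
    n-1 merges in execution order with non-decreasing heights.
    """

    leaves: list[str]
    merges: list[Merge]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValidationError("a tree over n leaves needs exactly n-1 merges")
        used: set[int] = set()
        heights = [m.height for m in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")
        for i, m in enumerate(self.merges):
            for child in (m.left, m.right):
                if child in used or not (0 <= child < n + i):
                    raise ValidationError("invalid merge structure")
                used.add(child)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n].height

    def members(self, node: int) -> frozenset[int]:
        """Leaf indices under a node."""
        n = self.n_leaves
        if node < n:
            return frozenset([node])
        m = self.merges[node - n]
        return self.members(m.left) | self.members(m.right)

    def cophenetic(self) -> np.ndarray:
        """Matrix of merge heights at which each leaf pair first joins."""
        n = self.n_leaves
        coph = np.zeros((n, n))
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, m in enumerate(self.merges):
            a, b = sets.pop(m.left), sets.pop(m.right)
            for i in a:
                for j in b:
                    coph[i, j] = coph[j, i] = m.height
            sets[n + k] = a | b
        return coph

    def to_scipy_linkage(self) -> np.ndarray:
        """(n-1) x 4 linkage array usable with scipy dendrogram plotting."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((n - 1, 4))
        for k, m in enumerate(self.merges):
            size = sizes[m.left] + sizes[m.right]
            sizes[n + k] = size
            z[k] = [m.left, m.right, m.height, size]
        return z


def complete_linkage(dist: DistanceMatrix) -> LinkageTree:
    """Complete-linkage agglomeration of a labelled distance matrix."""
    n = len(dist.labels)
    if n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    d = dist.values
    if not np.isfinite(d).all():
        raise ValidationError("distance matrix contains non-finite entries")

    # inter-cluster distances keyed by creation index; clusters die on merge
    active: list[int] = list(range(n))
    cd: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        # smallest distance; ties -> lexicographically smallest (i, j)
        best = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda ij: (cd[ij], ij),
        )
        i, j = best
        h = cd[best]
        merges.append(Merge(i, j, h))
        active.remove(i)
        active.remove(j)
        for k in active:
            cd[(min(k, next_id), max(k, next_id))] = max(
                cd[(min(i, k), max(i, k))], cd[(min(j, k), max(j, k))]
            )
        active.append(next_id)
        next_id += 1
    return LinkageTree(list(dist.labels), merges)


def subtree_height(tree: LinkageTree, labels) -> float:
    """Height of the lowest tree node containing all given leaf labels
    (the cophenetic span of the set); 0 for a single leaf."""
    labels = list(labels)
    if not labels:
        raise ValidationError("labels must be non-empty")
    index = {lab: i for i, lab in enumerate(tree.leaves)}
    unknown = [l for l in labels if l not in index]
    if unknown:
        raise ValidationError("unknown leaf label(s): " + ", ".join(unknown))
    target = frozenset(index[l] for l in labels)
    if len(target) == 1:
        return 0.0
    n = tree.n_leaves
    for k, m in enumerate(tree.merges):  # heights non-decreasing => first hit is lowest
        if target <= tree.members(n + k):
            return m.height
    raise AssertionError("root must contain all leaves")  # pragma: no cover


def _quote_label(label: str) -> str:
    if not label or any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: LinkageTree) -> str:
    """Newick text with branch lengths; each leaf-to-root path length equals
    the root height (an ultrametric dendrogram)."""
    n = tree.n_leaves

    def render(node: int, parent_height: float) -> str:
        h = tree.node_height(node)
        branch = parent_height - h
        if node < n:
            return f"{_quote_label(tree.leaves[node])}:{branch:.10g}"
        m = tree.merges[node - n]
        return f"({render(m.left, h)},{render(m.right, h)}):{branch:.10g}"

    root_h = tree.merges[-1].height
    m = tree.merges[-1]
    return f"({render(m.left, root_h)},{render(m.right, root_h)});"
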