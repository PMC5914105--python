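"""Hierarchical cluster analysis with cosine distance and between-groups
(unweighted average / UPGMA) linkage.

"Between-groups linkage" follows the common statistical-package definition:
the distance between two clusters is the unweighted mean of all cross-pair
leaf distances.  Each step merges the globally closest pair; ties break
lexicographically on (smaller cluster id, larger cluster id) so the merge
sequence is reproducible.  Average linkage does not guarantee monotone merge
heights on an arbitrary dissimilarity; inversions are recorded on the tree,
not hidden.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprint import FingerprintVector

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "cosine_distance_matrix",
    "hca_between_groups",
    "cut_groups",
    "to_newick",
    "to_text",
    "to_scipy_linkage",
]


@dataclass
class DistanceMatrix:
    """Symmetric cosine-distance matrix with sample labels."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match the label count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-10) or np.any(self.values > 2.0 + 1e-10):
            raise ValueError("cosine distances must lie in [0, 2]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class LinkageTree:
    """Agglomerative merge history.

    ``merges`` lists ``(cluster_a, cluster_b, height, new_size)`` with leaves
    numbered 0..n-1 and the merge at step k creating cluster ``n + k`` (the
    scipy convention).  ``has_inversions`` is True when a merge height fell
    below an earlier one.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]
    has_inversions: bool = False

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def cosine_distance_matrix(vectors: Sequence[FingerprintVector]) -> DistanceMatrix:
    """d(x, y) = 1 - cos(x, y) for every pair of fingerprints."""
    if not vectors:
        raise ValueError("need at least one fingerprint")
    dim = vectors[0].values.size
    X = np.vstack([v.values for v in vectors])
    if X.shape[1] != dim:
        raise ValueError("fingerprints must share dimension")
    norms = np.linalg.norm(X, axis=1)
    for v, nrm in zip(vectors, norms):
        if nrm == 0:
            raise ValueError(f"sample {v.sample_id}: zero-norm fingerprint")
    cos = (X @ X.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(cos, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # kill rounding asymmetry
    return DistanceMatrix([v.sample_id for v in vectors], d)


def hca_between_groups(dm: DistanceMatrix) -> LinkageTree:
    """Agglomerative clustering with unweighted average (UPGMA) linkage.

    Inter-cluster distance is the mean of all cross-pair leaf distances from
    the original matrix; the globally minimal pair merges each step.
    """
    d = dm.values
    n = len(dm.ids)
    if n < 2:
        raise ValueError("clustering needs at least two samples")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    has_inversions = False
    last_height = -np.inf
    next_id = n
    while len(members) > 1:
        best: tuple[float, int, int] | None = None
        ids = sorted(members)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                dist = float(d[np.ix_(members[a], members[b])].mean())
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
                # ties keep the lexicographically first (a, b) pair
        dist, a, b = best  # type: ignore[misc]
        if dist < last_height - 1e-12:
            has_inversions = True
        last_height = dist
        members[next_id] = members.pop(a) + members.pop(b)
        merges.append((a, b, dist, len(members[next_id])))
        next_id += 1
    return LinkageTree(merges, list(dm.ids), has_inversions)


def cut_groups(tree: LinkageTree, k: int) -> dict[str, int]:
    """Partition into k groups by undoing the last k-1 merges.

    Returns ``sample_id -> group label`` with groups numbered 1..k in order of
    their smallest leaf index.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _h, _size) in enumerate(tree.merges[: n - k]):
        members[n + step] = members.pop(a) + members.pop(b)
    groups = sorted(members.values(), key=min)
    assignment: dict[str, int] = {}
    for label, leaves in enumerate(groups, start=1):
        for leaf in leaves:
            assignment[tree.leaf_ids[leaf]] = label
    return assignment


def to_scipy_linkage(tree: LinkageTree) -> np.ndarray:
    """Merge history as an (n-1) x 4 array in the scipy linkage layout."""
    return np.array([[a, b, h, s] for a, b, h, s in tree.merges], dtype=float)


def to_newick(tree: LinkageTree) -> str:
    """Newick string with merge heights as node depths (branch lengths are
    height differences; leaves sit at depth 0)."""
    n = tree.n_leaves
    node: dict[int, tuple[str, float]] = {
        i: (tree.leaf_ids[i], 0.0) for i in range(n)
    }
    for step, (a, b, h, _s) in enumerate(tree.merges):
        sa, ha = node.pop(a)
        sb, hb = node.pop(b)
        rep = f"({sa}:{max(h - ha, 0.0):.6g},{sb}:{max(h - hb, 0.0):.6g})"
        node[n + step] = (rep, h)
    (rep, _h), = node.values()
    return rep + ";"


def to_text(tree: LinkageTree, indent: str = "  ") -> str:
    """Indented text rendering of the dendrogram (merge heights annotated)."""
    n = tree.n_leaves
    node: dict[int, list[str]] = {i: [tree.leaf_ids[i]] for i in range(n)}
    for step, (a, b, h, _s) in enumerate(tree.merges):
        sub = [f"+ height {h:.6g}"]
        for child in (a, b):
            sub.extend(indent + line for line in node.pop(child))
        node[n + step] = sub
    (lines,) = node.values()
    return "\n".join(lines)
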