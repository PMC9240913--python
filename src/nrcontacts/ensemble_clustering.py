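"""Contact-map dissimilarity and hierarchical clustering of an ensemble.

Two binary contact maps are compared by N10 — the number of cells in which
they differ (XOR count; for binary entries Σ(a−b)² is exactly that count) —
or by 1/N11, the reciprocal of the number of contacts formed in both maps.
Cells are counted once per unordered residue pair (upper triangle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import squareform

from .contacts import ContactMatrix
from .errors import EnsembleError, WindowError


def _check_compatible(a: ContactMatrix, b: ContactMatrix) -> None:
    if not a.same_window(b):
        raise WindowError(
            f"window mismatch: [{a.lo},{a.hi}] vs [{b.lo},{b.hi}] "
            "(restrict both maps to the common region first)"
        )
    if a.min_seq_sep != b.min_seq_sep:
        raise WindowError("contact maps use different neighbour-exclusion rules")


def n10(a: ContactMatrix, b: ContactMatrix, full_matrix: bool = False) -> int:
    """Number of differing cells between two binary contact maps.

    By default each unordered pair is counted once; ``full_matrix=True``
    counts the symmetric cell twice (the whole-matrix summation convention).
    The two conventions differ by an exact factor of two and give identical
    clusterings.
    """
    _check_compatible(a, b)
    diff = int(np.sum(np.triu(a.entries ^ b.entries, k=1)))
    return 2 * diff if full_matrix else diff


def n11(a: ContactMatrix, b: ContactMatrix, full_matrix: bool = False) -> int:
    """Number of contacts formed in both maps (AND count)."""
    _check_compatible(a, b)
    both = int(np.sum(np.triu(a.entries & b.entries, k=1)))
    return 2 * both if full_matrix else both


def inverse_n11_distance(a: ContactMatrix, b: ContactMatrix) -> float:
    """1/N11 dissimilarity; infinite when the maps share no contact (the
    caller replaces infinities with a sentinel, see
    :func:`dissimilarity_matrix`)."""
    shared = n11(a, b)
    return float("inf") if shared == 0 else 1.0 / shared


@dataclass(frozen=True)
class DissimilarityMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # (K, K) symmetric, zero diagonal
    metric: str  # "n10" | "inverse_n11"

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise EnsembleError("dissimilarity matrix shape does not match ids")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise EnsembleError("dissimilarity matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "d", d)

    def to_csv(self) -> str:
        import pandas as pd

        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids)).to_csv()


def dissimilarity_matrix(
    maps: list[ContactMatrix],
    ids: list[str] | None = None,
    metric: str = "n10",
    full_matrix: bool = False,
) -> DissimilarityMatrix:
    """All-pairs dissimilarity of an ensemble of contact maps.

    For the ``inverse_n11`` metric, disjoint pairs (N11 = 0) receive a
    documented sentinel: ten times the largest finite distance in the matrix
    (or 10.0 if every pair is disjoint), keeping the matrix finite for
    linkage."""
    if ids is None:
        ids = [m.structure_id or f"s{k}" for k, m in enumerate(maps)]
    if len(ids) != len(maps):
        raise EnsembleError("ids and maps differ in length")
    K = len(maps)
    d = np.zeros((K, K), dtype=float)
    for p in range(K):
        for q in range(p + 1, K):
            if metric == "n10":
                v = float(n10(maps[p], maps[q], full_matrix=full_matrix))
            elif metric == "inverse_n11":
                v = inverse_n11_distance(maps[p], maps[q])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[p, q] = d[q, p] = v
    if metric == "inverse_n11" and np.isinf(d).any():
        finite = d[np.isfinite(d)]
        sentinel = 10.0 * float(finite.max()) if finite.size and finite.max() > 0 else 10.0
        d[np.isinf(d)] = sentinel
    return DissimilarityMatrix(ids=tuple(ids), d=d, metric=metric)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over the structure ensemble."""

    leaf_ids: tuple[str, ...]
    Z: np.ndarray  # scipy linkage matrix
    linkage_method: str

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = cut_tree(self.Z, n_clusters=n_clusters).ravel()
        return {sid: int(c) for sid, c in zip(self.leaf_ids, labels)}

    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2].copy()

    def to_newick(self) -> str:
        """Newick text with branch lengths (leaf height = merge height/2 under
        UPGMA semantics; internal branch = height difference)."""
        root = to_tree(self.Z)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0) / 2.0
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{parent_height / 2.0:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist).rsplit(":", 1)[0] + ";"


def hierarchical_cluster(d: DissimilarityMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering (UPGMA by default) of the dissimilarity
    matrix.  Structures are processed in lexicographic id order so ties are
    broken deterministically run-to-run."""
    if len(d.ids) < 2:
        raise EnsembleError("clustering requires at least two structures")
    order = np.argsort(np.asarray(d.ids))
    ids = tuple(d.ids[k] for k in order)
    dm = d.d[np.ix_(order, order)]
    Z = linkage(squareform(dm, checks=False), method=method)
    return Dendrogram(leaf_ids=ids, Z=Z, linkage_method=method)
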