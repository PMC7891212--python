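"""Network construction: OMST thresholding, structural masking, supra assembly.

The z-scored coupling matrices are dense and noisy; the orthogonal
minimum spanning tree (OMST) scheme thresholds each one in a data-driven
way by accumulating successive edge-disjoint maximum-weight spanning
trees while a global cost-efficiency objective improves.  Surviving
edges are then masked entry-wise by the binary anatomical (tractography)
matrix, and the per-layer-pair matrices are assembled into the
supra-adjacency matrix of the full multilayer network.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .datatypes import ConnectivityBlock, OMSTResult, StructuralMatrix, SupraAdjacency

__all__ = [
    "omst",
    "apply_structural_mask",
    "assemble_supra",
    "sparsity",
    "global_efficiency",
]


def global_efficiency(weights: np.ndarray) -> float:
    """Weighted global efficiency: mean over node pairs of 1/shortest-distance.

    Edge distance is the reciprocal of edge weight; disconnected pairs
    contribute zero.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(dist, 0.0)
    d = shortest_path(dist, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _max_spanning_tree(
    n: int, edges: list[tuple[float, int, int]]
) -> list[tuple[float, int, int]] | None:
    """Kruskal maximum-weight spanning tree; None if the edges do not span.

    Ties on weight break lexicographically by (i, j) for determinism.
    """
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = []
    for w, i, j in sorted(edges, key=lambda e: (-e[0], e[1], e[2])):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((w, i, j))
            if len(tree) == n - 1:
                return tree
    return None


def _max_spanning_forest(
    n: int, edges: list[tuple[float, int, int]]
) -> list[tuple[float, int, int]]:
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    forest = []
    for w, i, j in sorted(edges, key=lambda e: (-e[0], e[1], e[2])):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            forest.append((w, i, j))
    return forest


def omst(weights: np.ndarray, max_rounds: int = 20) -> OMSTResult:
    """Orthogonal-MST thresholding of a symmetric nonnegative matrix.

    Round m extracts the maximum-weight spanning tree over edges not
    retained in rounds 1..m-1 (MST on distances 1/w).  After each round
    the global cost-efficiency objective

        J(m) = GE(union of rounds 1..m) / GE(full graph) - Cost(m),
        Cost(m) = sum of retained weights / sum of all input weights,

    is evaluated, and the returned network is the union over the prefix
    of rounds that maximizes J.  Rounds stop early when the unused edges
    no longer contain a spanning tree.  If even the full input is
    disconnected, the first round falls back to the maximum spanning
    forest and the result is flagged (``connected=False``).
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diag(w) != 0):
        raise ValueError("diagonal must be zero")

    iu, ju = np.triu_indices(n, k=1)
    mask = w[iu, ju] > 0
    edges = [(float(w[i, j]), int(i), int(j)) for i, j in zip(iu[mask], ju[mask])]
    total_weight = sum(e[0] for e in edges)
    if total_weight == 0:
        raise ValueError("empty graph: no positive weights to threshold")

    ge_full = global_efficiency(w)
    used: set[tuple[int, int]] = set()
    retained = np.zeros_like(w)
    connected = True
    curve: list[float] = []
    prefix_mats: list[np.ndarray] = []

    for m in range(max_rounds):
        avail = [e for e in edges if (e[1], e[2]) not in used]
        tree = _max_spanning_tree(n, avail)
        if tree is None:
            if m == 0:
                tree = _max_spanning_forest(n, avail)
                connected = False
                if not tree:
                    break
            else:
                break
        for wgt, i, j in tree:
            used.add((i, j))
            retained[i, j] = retained[j, i] = wgt
        cost = sum(w[i, j] for i, j in used) / total_weight
        ge = global_efficiency(retained) / ge_full if ge_full > 0 else 0.0
        curve.append(ge - cost)
        prefix_mats.append(retained.copy())
        if not connected:
            break

    best = int(np.argmax(curve))
    return OMSTResult(
        retained=prefix_mats[best],
        n_rounds=best + 1,
        gce_curve=curve,
        connected=connected,
    )


def apply_structural_mask(block: np.ndarray, sc: StructuralMatrix) -> np.ndarray:
    """Entry-wise product of a coupling matrix with the binary structural matrix."""
    b = np.asarray(block, dtype=float)
    if b.shape != sc.mat.shape:
        raise ValueError(f"block shape {b.shape} != structural shape {sc.mat.shape}")
    return b * sc.mat


def assemble_supra(
    blocks: list[ConnectivityBlock],
    n_nodes: int,
    n_layers: int,
    labels: list[str] | None = None,
) -> SupraAdjacency:
    """Stack layer-pair matrices into the (N*B) x (N*B) supra-adjacency.

    Expects exactly B within blocks and B(B-1)/2 between blocks, each
    N x N; between blocks must already be symmetric (max-symmetrized).
    Block (a, b) with a < b is placed above the diagonal and its
    transpose below, so the supra matrix is symmetric.
    """
    B, N = n_layers, n_nodes
    expected = {(a, a) for a in range(B)} | {
        (a, b) for a in range(B) for b in range(a + 1, B)
    }
    got = {(blk.binA, blk.binB) for blk in blocks}
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"bad block set: missing layer pairs {missing}, unexpected {extra}"
        )
    supra = np.zeros((N * B, N * B))
    for blk in blocks:
        if blk.mat.shape != (N, N):
            raise ValueError(
                f"block {(blk.binA, blk.binB)} has shape {blk.mat.shape}, "
                f"expected ({N}, {N})"
            )
        a, b = blk.binA, blk.binB
        m = blk.mat
        if not np.allclose(m, m.T):
            raise ValueError(
                f"block {(a, b)} is not symmetric; apply symmetrize_max first"
            )
        supra[a * N : (a + 1) * N, b * N : (b + 1) * N] = m
        if a != b:
            supra[b * N : (b + 1) * N, a * N : (a + 1) * N] = m.T
    mat = np.maximum(supra, 0.0)
    np.fill_diagonal(mat, 0.0)
    return SupraAdjacency(
        n_nodes=N, n_layers=B, mat=mat, labels=list(labels) if labels else []
    )


def sparsity(mat: np.ndarray) -> float:
    """Fraction of possible (undirected, off-diagonal) edges present."""
    m = np.asarray(mat)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    return float(np.count_nonzero(m[iu, ju]) / (n * (n - 1) / 2))


def is_connected(mat: np.ndarray) -> bool:
    """True if the weighted graph is a single connected component."""
    ncomp, _ = connected_components(np.asarray(mat) != 0, directed=False)
    return bool(ncomp == 1)
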