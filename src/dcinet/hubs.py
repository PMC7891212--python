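"""Connector-hub statistics on the full multilayer network.

Candidate hubs are nodes whose multilayer versatility — a PageRank-style
random-walk centrality on the supra-adjacency graph, aggregated over a
node's layer replicas — stands out (z > 2) from the rest of the network.
Each candidate is then scored by delta centrality on interconnectedness
(DCI): the percent drop in the number of interlayer edges when the node
and all its layer replicas are removed.  Nodes whose scaled DCI is
consistently positive across subjects (one-tailed sign-flip permutation
test) are the group-level connector hubs.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import DCIResult, GroupResult, HubTable, SupraAdjacency

__all__ = [
    "versatility",
    "zscore_nodes",
    "detect_hubs",
    "hub_table",
    "interconnectedness",
    "dci",
    "dci_profile",
    "group_test",
]

logger = logging.getLogger(__name__)

# full sign enumeration is used when 2^n_subjects does not exceed this
_EXACT_ENUM_LIMIT = 4096


def versatility(
    supra: SupraAdjacency,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Multilayer versatility: PageRank on the supra graph, summed over layers.

    The random walk runs on the N*B node-layer graph with
    column-normalized transition probabilities and uniform teleportation
    at rate ``1 - damping``; dangling node-layers (zero strength)
    teleport uniformly.  The stationary distribution is aggregated by
    summing each physical node's probability over its B layer replicas,
    so the returned vector sums to 1.  With a single layer this is
    exactly ordinary PageRank.
    """
    if not (0 < damping < 1):
        raise ValueError("damping must lie in (0, 1)")
    W = supra.mat
    nb = W.shape[0]
    strength = W.sum(axis=0)
    if not strength.any():
        raise ValueError("all-zero supra-adjacency: versatility undefined")
    dangling = strength == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(dangling[None, :], 0.0, W / np.where(dangling, 1.0, strength))
    v = np.full(nb, 1.0 / nb)
    for _ in range(max_iter):
        v_new = damping * (T @ v + v[dangling].sum() / nb) + (1 - damping) / nb
        if np.abs(v_new - v).sum() < tol:
            v = v_new
            break
        v = v_new
    v = v / v.sum()
    return v.reshape(supra.n_layers, supra.n_nodes).sum(axis=0)


def zscore_nodes(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize a score vector to mean 0, sd 1 (population sd by default)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = v.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant vector")
    return (v - v.mean()) / sd


def detect_hubs(z: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Hub flags: strictly z > threshold."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    flags = z > threshold
    if not flags.any():
        logger.info("no node exceeds z > %g: empty hub set", threshold)
    return flags


def hub_table(
    supra: SupraAdjacency,
    damping: float = 0.85,
    tol: float = 1e-10,
    hub_threshold: float = 2.0,
    ddof: int = 0,
) -> HubTable:
    """Versatility, z-score and hub flag for every node."""
    v = versatility(supra, damping=damping, tol=tol)
    z = zscore_nodes(v, ddof=ddof)
    return HubTable(
        labels=list(supra.labels),
        versatility=v,
        z_versatility=z,
        is_hub=detect_hubs(z, hub_threshold),
        hub_threshold=hub_threshold,
    )


def interconnectedness(supra: SupraAdjacency, count_replica_pairs: bool = True) -> int:
    """Number of interlayer connections in the multilayer network.

    Counts each undirected interlayer edge once: nonzero entries of the
    off-diagonal blocks (a, b) with a < b, over all node pairs including
    a node's own replica pair (i in layer a — i in layer b) unless
    ``count_replica_pairs`` is False.
    """
    total = 0
    for a in range(supra.n_layers):
        for b in range(a + 1, supra.n_layers):
            blk = supra.block(a, b)
            c = int(np.count_nonzero(blk))
            if not count_replica_pairs:
                c -= int(np.count_nonzero(np.diag(blk)))
            total += c
    return total


def dci(supra: SupraAdjacency, node: int, count_replica_pairs: bool = True) -> float:
    """Delta centrality on interconnectedness for one node, in percent.

    Removes all B layer replicas of ``node`` (zeroing their rows and
    columns) and reports ``100 * (I_full - I_removed) / I_full``, where I
    is the interlayer edge count.  Positive values mean the node's
    removal reduces cross-frequency connectivity.
    """
    if not (0 <= node < supra.n_nodes):
        raise ValueError(f"node {node} out of range [0, {supra.n_nodes})")
    i_full = interconnectedness(supra, count_replica_pairs)
    if i_full == 0:
        raise ValueError("interconnectedness is zero: DCI undefined")
    mat = supra.mat.copy()
    idx = [a * supra.n_nodes + node for a in range(supra.n_layers)]
    mat[idx, :] = 0.0
    mat[:, idx] = 0.0
    removed = SupraAdjacency(supra.n_nodes, supra.n_layers, mat, list(supra.labels))
    i_removed = interconnectedness(removed, count_replica_pairs)
    return 100.0 * (i_full - i_removed) / i_full


def dci_profile(
    supra: SupraAdjacency,
    candidates: np.ndarray,
    count_replica_pairs: bool = True,
) -> DCIResult:
    """Raw and scaled DCI over a set of candidate (hub) nodes.

    Because most DCI values are exactly zero, scaling divides by the
    standard deviation over candidates without subtracting the mean, so
    the meaningful zero point is preserved; if all candidates tie
    (sd = 0) the raw values are passed through unchanged.
    """
    cand = np.asarray(candidates, dtype=int)
    if cand.size == 0:
        raise ValueError("candidate set is empty")
    raw = np.array([dci(supra, int(c), count_replica_pairs) for c in cand])
    sd = raw.std(ddof=0)
    scaled = raw / sd if sd > 0 else raw.copy()
    return DCIResult(
        candidates=cand,
        dci_raw=raw,
        dci_scaled=scaled,
        interconnectedness_full=interconnectedness(supra, count_replica_pairs),
    )


def group_test(
    values: np.ndarray,
    n_permutations: int = 5000,
    seed: int | None = None,
    labels: list[str] | None = None,
    candidates: np.ndarray | None = None,
) -> GroupResult:
    """One-sample, one-tailed sign-flip permutation test per node.

    ``values`` is a subject x node matrix of scaled DCI scores.  The
    observed statistic per node is the mean over subjects; the null is
    built by randomly negating each subject's value (exchangeability of
    sign under the no-effect hypothesis).  When ``2^n_subjects`` is
    small enough (<= 4096) all sign patterns are enumerated and the p
    value is exact (``#{null mean >= observed} / 2^n``); otherwise
    ``n_permutations`` random flips are drawn and the add-one estimate
    ``(1 + #{null >= obs}) / (1 + n_permutations)`` keeps p strictly
    positive.  Nodes with all-zero values across subjects get p = 1 and
    are flagged.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    n_sub, n_nodes = X.shape
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    obs = X.mean(axis=0)
    all_zero = ~X.any(axis=0)

    exact = 2**n_sub <= _EXACT_ENUM_LIMIT
    eps = 1e-12
    if exact:
        # all 2^n sign patterns as a (2^n, n) matrix of +-1
        bits = (np.arange(2**n_sub)[:, None] >> np.arange(n_sub)) & 1
        signs = 1 - 2 * bits.astype(float)
        null_means = (signs @ X) / n_sub  # (2^n, nodes)
        p = (null_means >= obs - eps).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
        null_means = (signs @ X) / n_sub
        p = (1 + (null_means >= obs - eps).sum(axis=0)) / (1 + n_permutations)
    p = np.where(all_zero, 1.0, p)
    if all_zero.any():
        logger.warning("%d node(s) with all-zero values across subjects", all_zero.sum())
    return GroupResult(
        labels=list(labels) if labels else [f"node{i:03d}" for i in range(n_nodes)],
        candidates=(
            np.asarray(candidates, dtype=int)
            if candidates is not None
            else np.arange(n_nodes)
        ),
        effect_size=obs,
        p_value=p,
        n_subjects=n_sub,
        exact=exact,
        all_zero=all_zero,
    )
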