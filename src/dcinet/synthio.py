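"""Synthetic data with planted structure for every pipeline stage.

Three generators, one per level of the pipeline:

* a modular binary structural matrix (stochastic block model, rejected
  until connected) standing in for binarized tractography;
* band-limited oscillatory source time series with 1/f-plus-white
  background noise, in which chosen node pairs share a slow amplitude
  modulator between named frequency bins — exactly the statistical
  structure amplitude–amplitude coupling measures, and nothing more;
* a direct supra-adjacency fixture with a planted connector node that
  carries at least twice the interlayer edges of any other node, for
  unit-testing the network stages in isolation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.sparse.csgraph import connected_components

from .datatypes import FrequencyBin, SourceTimeSeriesSet, StructuralMatrix, SupraAdjacency

__all__ = [
    "SynthConfig",
    "generate_structural_matrix",
    "generate_coupled_timeseries",
    "generate_multilayer_fixture",
    "connector_hub_config",
]


@dataclass
class SynthConfig:
    """Recipe for coupled oscillatory sources.

    ``planted_pairs`` entries are ``(node_i, node_j, binA, binB,
    coupling_strength)``: the band-``binA`` envelope of node i and the
    band-``binB`` envelope of node j share a common slow modulator with
    mixing weight ``coupling_strength`` in [0, 1].  ``hub_node``, if
    set, is the index of a planted connector node (validated to appear
    in at least 3 distinct bin pairs among the planted couplings).
    """

    n_nodes: int = 12
    n_trials: int = 5
    fs: float = 300.0
    epoch: tuple[float, float] = (0.0, 2.0)
    bins: list[FrequencyBin] = field(default_factory=list)
    planted_pairs: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    hub_node: int | None = None
    noise: tuple[float, float] = (1.0, 0.3)  # (1/f exponent alpha, white sd)
    oscillation_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bins:
            # study layout: ten 5 Hz bins, 0.5-50.5 Hz
            self.bins = [
                FrequencyBin(0.5 + 5 * k, 5.5 + 5 * k) for k in range(10)
            ]
        high = max(b.high_hz for b in self.bins)
        if self.fs <= 2 * high:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest bin edge ({high} Hz)"
            )
        for i, j, a, b, s in self.planted_pairs:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"planted pair ({i}, {j}) references invalid nodes")
            if not (0 <= a < len(self.bins) and 0 <= b < len(self.bins)):
                raise ValueError(f"planted pair bins ({a}, {b}) out of range")
            if not (0 <= s <= 1):
                raise ValueError(f"coupling strength {s} outside [0, 1]")
        if self.hub_node is not None:
            if not (0 <= self.hub_node < self.n_nodes):
                raise ValueError(f"hub_node {self.hub_node} out of range")
            pairs = {
                (a, b)
                for i, j, a, b, _ in self.planted_pairs
                if self.hub_node in (i, j)
            }
            if len(pairs) < 3:
                raise ValueError(
                    "hub_node couplings must span at least 3 frequency-bin pairs"
                )


def generate_structural_matrix(
    n_nodes: int,
    edge_density: float,
    n_modules: int = 1,
    seed: int | None = None,
    ensure_connected: bool = True,
    within_between_ratio: float = 4.0,
    max_attempts: int = 200,
) -> StructuralMatrix:
    """Modular binary structural backbone (stochastic block model).

    Nodes are assigned to ``n_modules`` blocks round-robin; within-module
    pairs get a ``within_between_ratio`` times higher edge probability
    than between-module pairs, with both calibrated so the expected
    overall density equals ``edge_density``.  Sampling is rejected until
    the graph is connected (when ``ensure_connected``).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must lie in (0, 1]")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    n_pairs = n_nodes * (n_nodes - 1) / 2
    if ensure_connected and edge_density * n_pairs < n_nodes - 1:
        raise ValueError(
            f"density {edge_density} yields ~{edge_density * n_pairs:.1f} edges, "
            f"fewer than the {n_nodes - 1} needed for connectivity"
        )

    modules = np.arange(n_nodes) % n_modules
    iu, ju = np.triu_indices(n_nodes, k=1)
    same = modules[iu] == modules[ju]
    frac_within = same.mean()
    # p_in = ratio * p_out, frac_within*p_in + (1-frac_within)*p_out = density
    p_out = edge_density / (frac_within * within_between_ratio + (1 - frac_within))
    p_in = min(1.0, within_between_ratio * p_out)
    if p_in == 1.0 and frac_within < 1.0:  # re-balance after clipping
        p_out = min(1.0, (edge_density - frac_within) / (1 - frac_within))
        p_out = max(p_out, 0.0)
    probs = np.where(same, p_in, p_out)

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        upper = rng.random(iu.size) < probs
        mat = np.zeros((n_nodes, n_nodes), dtype=int)
        mat[iu[upper], ju[upper]] = 1
        mat += mat.T
        if not ensure_connected:
            break
        ncomp, _ = connected_components(mat, directed=False)
        if ncomp == 1:
            break
    else:
        raise ValueError(
            f"no connected graph found in {max_attempts} attempts at "
            f"density {edge_density}"
        )
    return StructuralMatrix(mat=mat)


def _one_over_f_noise(
    rng: np.random.Generator, alpha: float, n: int, fs: float
) -> np.ndarray:
    """Unit-sd Gaussian noise spectrally shaped to 1/f^alpha."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_modulator(rng: np.random.Generator, n: int, fs: float, cutoff: float = 1.0) -> np.ndarray:
    """Positive slow amplitude modulator with unit mean, sd ~0.4."""
    z = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, z)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    return np.clip(1.0 + 0.4 * slow, 0.05, None)


def generate_coupled_timeseries(cfg: SynthConfig) -> SourceTimeSeriesSet:
    """Oscillatory sources with planted within/cross-frequency envelope coupling.

    Each planted pair contributes a sinusoidal carrier at its bin's
    center frequency to both nodes; the carrier amplitudes are
    ``(1 - s) * own + s * shared`` mixes of independent and shared slow
    modulators, so the band envelopes of the two nodes correlate with a
    strength that increases monotonically with ``s`` and is zero at
    ``s = 0``.  Background is 1/f^alpha-shaped noise plus white noise.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round((cfg.epoch[1] - cfg.epoch[0]) * cfg.fs))
    t = np.arange(n_samples) / cfg.fs
    alpha, white_sd = cfg.noise
    data = np.zeros((cfg.n_nodes, n_samples, cfg.n_trials))

    for trial in range(cfg.n_trials):
        for node in range(cfg.n_nodes):
            data[node, :, trial] = _one_over_f_noise(
                rng, alpha, n_samples, cfg.fs
            ) + white_sd * rng.standard_normal(n_samples)
        for i, j, a, b, s in cfg.planted_pairs:
            shared = _slow_modulator(rng, n_samples, cfg.fs)
            own_i = _slow_modulator(rng, n_samples, cfg.fs)
            own_j = _slow_modulator(rng, n_samples, cfg.fs)
            env_i = (1 - s) * own_i + s * shared
            env_j = (1 - s) * own_j + s * shared
            f_a, f_b = cfg.bins[a].center, cfg.bins[b].center
            phase_i = rng.uniform(0, 2 * np.pi)
            phase_j = rng.uniform(0, 2 * np.pi)
            data[i, :, trial] += (
                cfg.oscillation_amp * env_i * np.sin(2 * np.pi * f_a * t + phase_i)
            )
            data[j, :, trial] += (
                cfg.oscillation_amp * env_j * np.sin(2 * np.pi * f_b * t + phase_j)
            )
    labels = [f"node{i:03d}" for i in range(cfg.n_nodes)]
    return SourceTimeSeriesSet(data, cfg.fs, cfg.epoch, labels)


def connector_hub_config(
    hub_node: int = 0,
    n_nodes: int = 12,
    partners: list[int] | None = None,
    bin_pairs: list[tuple[int, int]] | None = None,
    coupling_strength: float = 0.9,
    **kwargs,
) -> SynthConfig:
    """Convenience recipe planting one connector node coupled across >=3 bin pairs."""
    if partners is None:
        partners = [(hub_node + k) % n_nodes for k in range(1, 5)]
    if bin_pairs is None:
        bin_pairs = [(0, 1), (0, 2), (1, 2), (0, 3)]
    pairs = [
        (hub_node, p, a, b, coupling_strength)
        for p, (a, b) in zip(partners, bin_pairs)
    ]
    return SynthConfig(
        n_nodes=n_nodes, planted_pairs=pairs, hub_node=hub_node, **kwargs
    )


def generate_multilayer_fixture(
    n_nodes: int,
    n_bins: int,
    intralayer_density: float = 0.3,
    interlayer_density: float = 0.1,
    planted_hub: int = 0,
    seed: int | None = None,
) -> SupraAdjacency:
    """Random supra-adjacency with a planted connector node.

    Within-frequency layers are random symmetric weighted graphs at
    ``intralayer_density``.  Interlayer edges among non-hub pairs are
    sampled at ``interlayer_density``; the planted hub is then given at
    least twice the interlayer edge count of the busiest other node (and
    none at all when ``interlayer_density`` is zero, so the
    zero-interlayer case stays exactly empty).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 layers for interlayer structure")
    if not (0 <= intralayer_density <= 1 and 0 <= interlayer_density <= 1):
        raise ValueError("densities must lie in [0, 1]")
    if not (0 <= planted_hub < n_nodes):
        raise ValueError(f"planted_hub {planted_hub} out of range")
    rng = np.random.default_rng(seed)
    N, B = n_nodes, n_bins
    supra = np.zeros((N * B, N * B))

    iu, ju = np.triu_indices(N, k=1)
    for a in range(B):
        keep = rng.random(iu.size) < intralayer_density
        w = np.zeros((N, N))
        w[iu[keep], ju[keep]] = rng.uniform(0.5, 1.5, size=int(keep.sum()))
        w += w.T
        supra[a * N : (a + 1) * N, a * N : (a + 1) * N] = w

    if interlayer_density > 0:
        counts = np.zeros(N, dtype=int)
        hub_slots = []
        for a in range(B):
            for b in range(a + 1, B):
                blk = np.zeros((N, N))
                for i in range(N):
                    for j in range(N):
                        if planted_hub in (i, j):
                            hub_slots.append((a, b, i, j))
                        elif rng.random() < interlayer_density:
                            blk[i, j] = rng.uniform(0.5, 1.5)
                            counts[i] += 1
                            if j != i:
                                counts[j] += 1
                supra[a * N : (a + 1) * N, b * N : (b + 1) * N] = blk
                supra[b * N : (b + 1) * N, a * N : (a + 1) * N] = blk.T
        # keep adding hub edges until the hub has >= 2x the busiest other node,
        # recounting as partners gain edges from the hub's own additions
        order = rng.permutation(len(hub_slots))
        pos = 0
        others = np.ones(N, dtype=bool)
        others[planted_hub] = False
        while (
            counts[planted_hub] < max(2, 2 * int(counts[others].max()))
            and pos < len(order)
        ):
            a, b, i, j = hub_slots[order[pos]]
            pos += 1
            n0, n1 = a * N + i, b * N + j
            if supra[n0, n1] != 0:
                continue
            supra[n0, n1] = supra[n1, n0] = rng.uniform(0.5, 1.5)
            counts[planted_hub] += 1
            partner = j if i == planted_hub else i
            if partner != planted_hub:
                counts[partner] += 1
    np.fill_diagonal(supra, 0.0)
    return SupraAdjacency(n_nodes=N, n_layers=B, mat=supra)
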