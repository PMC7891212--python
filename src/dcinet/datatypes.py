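"""Shared containers for the multilayer connectivity pipeline.

The pipeline moves through a fixed sequence of representations: source
time series -> band-limited amplitude envelopes -> pairwise coupling
blocks -> a supra-adjacency matrix -> per-node hub statistics.  Each
stage's container lives here so the stage modules stay free of circular
imports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SourceTimeSeriesSet:
    """Source-space time series: ``data[node, sample, trial]``.

    Parameters
    ----------
    data : ndarray, shape (n_nodes, n_samples, n_trials)
        Real-valued source activity.
    fs : float
        Sampling rate in Hz.
    epoch : tuple of float
        ``(t_start, t_end)`` of the samples relative to stimulus onset,
        in seconds.
    labels : list of str
        Node (region) names, length ``n_nodes``.
    """

    data: np.ndarray
    fs: float
    epoch: tuple[float, float]
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (nodes, samples, trials); got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        t0, t1 = self.epoch
        expected = (t1 - t0) * self.fs
        if abs(self.data.shape[1] - expected) > 1 + 1e-6:
            raise ValueError(
                f"sample count {self.data.shape[1]} inconsistent with epoch "
                f"{self.epoch} at fs={self.fs} (expected ~{expected:.1f})"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.epoch[0] + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class FrequencyBin:
    """A frequency band ``[low_hz, high_hz)`` in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"invalid bin edges ({self.low_hz}, {self.high_hz})")

    @property
    def center(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.low_hz:g}-{self.high_hz:g}Hz"


@dataclass
class EnvelopeSet:
    """Per-bin Hilbert amplitude envelopes, cropped to the analysis window.

    ``envelopes[b]`` has shape ``(n_nodes, n_window_samples, n_trials)``
    and holds the nonnegative amplitude envelope of bin ``bins[b]``.
    """

    envelopes: list[np.ndarray]
    bins: list[FrequencyBin]
    window: tuple[float, float]
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.envelopes) != len(self.bins):
            raise ValueError("one envelope array required per bin")
        shapes = {e.shape for e in self.envelopes}
        if len(shapes) > 1:
            raise ValueError(f"envelope arrays have inconsistent shapes: {shapes}")
        for e in self.envelopes:
            if np.any(e < 0):
                raise ValueError("envelopes must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.envelopes[0].shape[0]

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class ConnectivityBlock:
    """One N x N coupling matrix for a layer pair ``(binA, binB)``.

    ``binA == binB`` is a within-frequency layer (symmetric, zero
    diagonal); ``binA < binB`` is a between-frequency (low -> high)
    block, symmetric only after max-symmetrization.
    """

    binA: int
    binB: int
    mat: np.ndarray

    def __post_init__(self) -> None:
        self.mat = np.asarray(self.mat, dtype=float)
        if self.mat.ndim != 2 or self.mat.shape[0] != self.mat.shape[1]:
            raise ValueError(f"block matrix must be square, got {self.mat.shape}")
        if self.binA > self.binB:
            raise ValueError("blocks are indexed low->high: binA <= binB required")

    @property
    def kind(self) -> str:
        return "within" if self.binA == self.binB else "between"

    @property
    def n_nodes(self) -> int:
        return self.mat.shape[0]


@dataclass
class StructuralMatrix:
    """Binary symmetric anatomical connectivity with zero diagonal."""

    mat: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mat = np.asarray(self.mat)
        m = self.mat
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("structural matrix must be square")
        if not np.array_equal(np.unique(m), np.unique(m).clip(0, 1)) or not np.isin(
            m, (0, 1)
        ).all():
            raise ValueError("structural matrix must be binary (0/1)")
        if not np.array_equal(m, m.T):
            raise ValueError("structural matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("structural matrix must have a zero diagonal")
        if not self.labels:
            self.labels = [f"node{i:03d}" for i in range(m.shape[0])]
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.mat.shape[0]


@dataclass
class SupraAdjacency:
    """The (N*B) x (N*B) supra-adjacency matrix of a full multilayer network.

    Row/column index ``a * n_nodes + i`` is node ``i``'s replica in layer
    ``a``.  Diagonal blocks hold within-frequency layers; off-diagonal
    block ``(a, b)`` with ``a < b`` holds the between-frequency coupling
    from bin ``a`` to bin ``b`` (its transpose sits at ``(b, a)``, so the
    full matrix is symmetric).
    """

    n_nodes: int
    n_layers: int
    mat: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mat = np.asarray(self.mat, dtype=float)
        nb = self.n_nodes * self.n_layers
        if self.mat.shape != (nb, nb):
            raise ValueError(
                f"supra matrix shape {self.mat.shape} != ({nb}, {nb}) for "
                f"N={self.n_nodes}, B={self.n_layers}"
            )
        if not np.allclose(self.mat, self.mat.T):
            raise ValueError("supra-adjacency must be symmetric")
        if np.any(self.mat < 0):
            raise ValueError("supra-adjacency must be nonnegative")
        if np.any(np.diag(self.mat) != 0):
            raise ValueError("supra-adjacency diagonal must be zero")
        if not self.labels:
            self.labels = [f"node{i:03d}" for i in range(self.n_nodes)]

    def block(self, a: int, b: int) -> np.ndarray:
        """Extract the N x N block for layer pair ``(a, b)``."""
        n = self.n_nodes
        return self.mat[a * n : (a + 1) * n, b * n : (b + 1) * n]


@dataclass
class OMSTResult:
    """Outcome of orthogonal-MST thresholding of one weighted layer."""

    retained: np.ndarray
    n_rounds: int
    gce_curve: list[float]
    connected: bool = True  # False => spanning-forest fallback was taken


@dataclass
class NullStats:
    """Surrogate-ensemble mean and standard deviation per connection.

    Keyed like the empirical blocks: ``mean[(a, b)]`` / ``sd[(a, b)]``
    are N x N matrices for the (binA=a, binB=b) layer pair.
    """

    mean: dict[tuple[int, int], np.ndarray]
    sd: dict[tuple[int, int], np.ndarray]
    n_surrogates: int

    def __post_init__(self) -> None:
        for key, s in self.sd.items():
            if np.any(s < 0):
                raise ValueError(f"negative null sd in block {key}")


@dataclass
class HubTable:
    """Per-node multilayer versatility, z-score and hub flag."""

    labels: list[str]
    versatility: np.ndarray
    z_versatility: np.ndarray
    is_hub: np.ndarray
    hub_threshold: float = 2.0

    def hub_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_hub)


@dataclass
class DCIResult:
    """Delta centrality on interconnectedness for a set of candidate nodes."""

    candidates: np.ndarray  # node indices the metric was evaluated on
    dci_raw: np.ndarray  # percent change in interconnectedness
    dci_scaled: np.ndarray  # unit-sd rescaling preserving the zero point
    interconnectedness_full: int


@dataclass
class GroupResult:
    """Group-level sign-flip permutation inference over candidate nodes."""

    labels: list[str]
    candidates: np.ndarray
    effect_size: np.ndarray  # mean scaled DCI across subjects
    p_value: np.ndarray
    n_subjects: int
    exact: bool  # True when the full 2^n sign enumeration was used
    all_zero: np.ndarray | None = None  # flags nodes with no signal anywhere


@dataclass
class AnalysisParams:
    """Tunable parameters of the hub-mapping stage with study defaults."""

    hub_threshold: float = 2.0
    n_surrogates: int = 100
    n_permutations: int = 5000
    pagerank_damping: float = 0.85
    pagerank_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.pagerank_damping < 1):
            raise ValueError("pagerank damping must lie in (0, 1)")
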