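"""Spectral preprocessing and amplitude–amplitude coupling (AAC).

Stages, in pipeline order: broadband band-pass + line-noise notch,
symmetric (leakage-reducing) orthogonalization, decomposition into
contiguous frequency bins, Hilbert amplitude envelopes cropped to the
analysis window, and Pearson-correlation AAC blocks for every within-
and between-bin layer pair (low -> high frequencies only).

All filters are applied zero-phase (forward–backward), so envelopes are
not phase-distorted; cropping always happens after filtering and the
Hilbert transform so edge artifacts stay outside the analysis window.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import ConnectivityBlock, EnvelopeSet, FrequencyBin, SourceTimeSeriesSet

__all__ = [
    "preprocess_broadband",
    "symmetric_orthogonalize",
    "make_bins",
    "band_envelopes",
    "aac",
    "connectivity_blocks",
    "symmetrize_max",
]


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def preprocess_broadband(
    ts: SourceTimeSeriesSet,
    band: tuple[float, float] = (0.1, 100.0),
    notch: float | None = 60.0,
    notch_q: float = 30.0,
) -> SourceTimeSeriesSet:
    """Zero-phase broadband band-pass plus a line-noise notch.

    Parameters
    ----------
    ts : SourceTimeSeriesSet
        Raw source time series.
    band : (low, high)
        Band-pass edges in Hz; must lie strictly inside (0, fs/2).
    notch : float or None
        Line frequency to reject (None skips the notch).
    """
    sos = _bandpass_sos(band[0], band[1], ts.fs)
    # long reflection padding: the low cut's settling time dominates the edges
    padlen = min(ts.n_samples - 1, int(3 * ts.fs / band[0]))
    out = signal.sosfiltfilt(sos, ts.data, axis=1, padlen=padlen)
    if notch is not None:
        if notch >= ts.fs / 2:
            raise ValueError(f"notch {notch} Hz at or above Nyquist ({ts.fs / 2} Hz)")
        b, a = signal.iirnotch(notch, notch_q, fs=ts.fs)
        out = signal.filtfilt(b, a, out, axis=1, padlen=min(ts.n_samples - 1, 3000))
    return SourceTimeSeriesSet(out, ts.fs, ts.epoch, list(ts.labels))


def symmetric_orthogonalize(
    ts: SourceTimeSeriesSet, max_iter: int = 100, tol: float = 1e-12
) -> SourceTimeSeriesSet:
    """Closest set of mutually orthogonal node time courses (no node privileged).

    Finds, in the least-squares sense, the matrix with pairwise
    orthogonal rows nearest to the input: the node-by-time matrix is
    factored as ``Y = D O`` with orthonormal rows ``O`` and a diagonal
    scaling ``D``, and ``||X - Y||_F`` is minimized by
    alternating a polar-decomposition update of ``O`` with a rescaling
    update of ``D``.  Because the factorization treats all rows
    identically, no node is privileged over another.

    Trials are concatenated along time before the decomposition (the
    orthogonality constraint must hold over the full recording) and the
    result is split back into trials.

    Raises
    ------
    ValueError
        If the node time courses are linearly dependent (rank-deficient
        input has no unique nearest orthogonal set).
    """
    n, s, r = ts.data.shape
    X = ts.data.reshape(n, s * r)  # trials concatenated in time order
    if n > X.shape[1]:
        raise ValueError(
            f"cannot orthogonalize {n} nodes against only {X.shape[1]} samples"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < n:
        raise ValueError(
            f"rank-deficient input: row rank {rank} < {n} nodes; "
            "orthogonalization undefined"
        )

    A = X.T  # samples x nodes; find A ~ O @ D, O orthonormal columns
    d = np.linalg.norm(A, axis=0)
    err_prev = np.inf
    for _ in range(max_iter):
        U, _, Vt = np.linalg.svd(A * d, full_matrices=False)
        O = U @ Vt
        d = np.einsum("ij,ij->j", A, O)
        err = float(np.linalg.norm(A - O * d))
        if err_prev - err <= tol * max(err, 1.0):
            break
        err_prev = err
    Y = (O * d).T
    return SourceTimeSeriesSet(Y.reshape(n, s, r), ts.fs, ts.epoch, list(ts.labels))


def make_bins(
    low: float = 0.5, high: float = 50.5, width: float = 5.0
) -> list[FrequencyBin]:
    """Contiguous, equally spaced frequency bins covering [low, high].

    The range must divide exactly by ``width`` (no partial bins); the
    study default is ten 5 Hz bins from 0.5 to 50.5 Hz.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    n = (high - low) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"range ({low}, {high}) is not an integer number of {width} Hz bins"
        )
    n = int(round(n))
    if n < 1:
        raise ValueError("at least one bin required")
    return [FrequencyBin(low + k * width, low + (k + 1) * width) for k in range(n)]


def band_envelopes(
    ts: SourceTimeSeriesSet,
    bins: list[FrequencyBin],
    window: tuple[float, float] = (0.8, 1.3),
    filter_order: int = 4,
) -> EnvelopeSet:
    """Hilbert amplitude envelopes per frequency bin, cropped to ``window``.

    Each bin's band-pass filter and the Hilbert transform run on the
    full epoch, per trial; only then is the envelope cropped to the
    analysis window, so filter and analytic-signal edge effects fall
    outside it.
    """
    t0, t1 = ts.epoch
    w0, w1 = window
    if not (t0 <= w0 < w1 <= t1 + 1e-9):
        raise ValueError(f"window {window} outside epoch {ts.epoch}")
    nyq = ts.fs / 2.0
    for fb in bins:
        if fb.high_hz >= nyq:
            raise ValueError(f"bin {fb} exceeds Nyquist ({nyq} Hz)")
    i0 = int(round((w0 - t0) * ts.fs))
    i1 = int(round((w1 - t0) * ts.fs))
    envs = []
    for fb in bins:
        lo = max(fb.low_hz, 1e-3)  # a 0 Hz edge is treated as "from DC": tiny highpass
        sos = _bandpass_sos(lo, fb.high_hz, ts.fs, order=filter_order)
        padlen = min(ts.n_samples - 1, int(3 * ts.fs / lo))
        banded = signal.sosfiltfilt(sos, ts.data, axis=1, padlen=padlen)
        env = np.abs(signal.hilbert(banded, axis=1))
        envs.append(env[:, i0:i1, :])
    return EnvelopeSet(envs, list(bins), window, ts.fs, list(ts.labels))


def aac(env_x: np.ndarray, env_y: np.ndarray) -> float:
    """Amplitude–amplitude coupling: Pearson correlation of two envelopes."""
    x = np.asarray(env_x, dtype=float).ravel()
    y = np.asarray(env_y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("envelope vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero-variance envelope: degenerate connection")
    return float(np.clip((xd @ yd) / np.sqrt(sx * sy), -1.0, 1.0))


def _pooled(env: np.ndarray, trial_pooling: str) -> np.ndarray:
    """Flatten (nodes, samples, trials) for correlation computation."""
    if trial_pooling == "concatenate":
        # (N, S, R) -> (N, S*R): window samples of all trials end to end
        return env.transpose(0, 2, 1).reshape(env.shape[0], -1)
    raise ValueError(f"unknown trial pooling {trial_pooling!r}")


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross-correlation matrix corr(a_i, b_j)."""
    ad = a - a.mean(axis=1, keepdims=True)
    bd = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.einsum("ij,ij->i", ad, ad))
    sb = np.sqrt(np.einsum("ij,ij->i", bd, bd))
    if np.any(sa == 0) or np.any(sb == 0):
        bad = list(np.flatnonzero(sa == 0)) + list(np.flatnonzero(sb == 0))
        raise ValueError(f"zero-variance envelope for node(s) {sorted(set(bad))}")
    c = (ad @ bd.T) / np.outer(sa, sb)
    return np.clip(c, -1.0, 1.0)


def connectivity_blocks(
    env: EnvelopeSet, trial_pooling: str = "concatenate"
) -> list[ConnectivityBlock]:
    """All within- and between-bin AAC blocks, ordered low -> high.

    For B bins this yields exactly B within-frequency blocks (symmetric,
    zero diagonal) and B(B-1)/2 between-frequency blocks whose raw
    ``[i, j]`` entry couples node ``i``'s low-bin envelope to node
    ``j``'s high-bin envelope (symmetrize with :func:`symmetrize_max`
    before network assembly).

    ``trial_pooling='concatenate'`` (default) correlates window samples
    concatenated across trials; ``'average'`` averages per-trial
    correlations instead.
    """
    if env.n_bins < 1 or env.n_nodes < 2:
        raise ValueError("need at least one bin and two nodes")
    B = env.n_bins

    def corr(a_idx: int, b_idx: int) -> np.ndarray:
        if trial_pooling == "average":
            n_trials = env.envelopes[0].shape[2]
            acc = np.zeros((env.n_nodes, env.n_nodes))
            for r in range(n_trials):
                acc += _corr_rows(
                    env.envelopes[a_idx][:, :, r], env.envelopes[b_idx][:, :, r]
                )
            return acc / n_trials
        return _corr_rows(
            _pooled(env.envelopes[a_idx], trial_pooling),
            _pooled(env.envelopes[b_idx], trial_pooling),
        )

    blocks: list[ConnectivityBlock] = []
    for a in range(B):
        m = corr(a, a)
        np.fill_diagonal(m, 0.0)
        blocks.append(ConnectivityBlock(a, a, m))
    for a in range(B):
        for b in range(a + 1, B):
            blocks.append(ConnectivityBlock(a, b, corr(a, b)))
    return blocks


def symmetrize_max(block: ConnectivityBlock) -> ConnectivityBlock:
    """Symmetrize a block by taking max(w_ij, w_ji); diagonal preserved."""
    m = block.mat
    out = np.maximum(m, m.T)
    np.fill_diagonal(out, np.diag(m))
    return ConnectivityBlock(block.binA, block.binB, out)
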