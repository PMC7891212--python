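"""IAAFT surrogate normalization of amplitude-coupling matrices.

Empirical AAC values are converted to z-scores against a surrogate null:
each source time course is replaced by an iterative amplitude-adjusted
Fourier transform (IAAFT) surrogate that preserves its amplitude
distribution exactly and its power spectrum approximately while
destroying any genuine cross-node coupling.  The s-th surrogate of every
node together forms the s-th null dataset; re-running the spectral
pipeline over the ensemble yields a per-connection null mean and
standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    ConnectivityBlock,
    FrequencyBin,
    NullStats,
    SourceTimeSeriesSet,
)
from .spectral import band_envelopes, connectivity_blocks

__all__ = ["iaaft", "null_connectivity", "zscore_blocks"]

logger = logging.getLogger(__name__)


def iaaft(
    x: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = None,
    return_errors: bool = False,
):
    """One IAAFT surrogate of ``x``.

    Alternates two projections starting from a random shuffle of ``x``:
    (i) impose the empirical power spectrum by replacing Fourier
    amplitudes while keeping current phases, then (ii) impose the
    empirical amplitude distribution by rank-remapping onto the sorted
    original values.  Iteration stops when the relative spectral error
    improves by less than ``tol`` or after ``max_iter`` rounds; the last
    step is always the rank remap, so the returned values are exactly a
    permutation of the input.

    Parameters
    ----------
    x : 1-D array, length >= 8, finite, non-constant.
    return_errors : bool
        Also return the per-iteration relative spectral amplitude error.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"need at least 8 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: no phase randomization possible")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    amp_norm = float(np.linalg.norm(target_amp))

    s = rng.permutation(x)
    errors: list[float] = []
    err_prev = np.inf
    for _ in range(max_iter):
        # (i) spectrum projection: keep phases, restore target amplitudes
        spec = np.fft.rfft(s)
        phase = np.angle(spec)
        s = np.fft.irfft(target_amp * np.exp(1j * phase), n=x.size)
        # (ii) amplitude projection: rank-remap onto the original values
        ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[ranks]
        err = float(np.linalg.norm(np.abs(np.fft.rfft(s)) - target_amp) / amp_norm)
        errors.append(err)
        if err_prev - err < tol * max(err, 1e-30):
            break
        err_prev = err
    if return_errors:
        return s, errors
    return s


def null_connectivity(
    ts: SourceTimeSeriesSet,
    bins: list[FrequencyBin],
    window: tuple[float, float] = (0.8, 1.3),
    n_surrogates: int = 100,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    trial_pooling: str = "concatenate",
) -> NullStats:
    """Per-connection null mean/sd from an IAAFT surrogate ensemble.

    Surrogates are generated from the full epoch of ``ts`` (one
    independent IAAFT realization per node, trial and surrogate index);
    for each surrogate index the whole spectral pipeline — band
    envelopes on the full epoch, crop to ``window``, AAC blocks — is
    re-run, and the ensemble mean and sample standard deviation (n-1
    denominator) are accumulated per connection.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates for a standard deviation")
    n, ns, r = ts.data.shape
    # one independent child stream per (surrogate, node, trial)
    streams = np.random.SeedSequence(seed).spawn(n_surrogates * n * r)

    acc_sum: dict[tuple[int, int], np.ndarray] | None = None
    acc_sq: dict[tuple[int, int], np.ndarray] | None = None
    for s_idx in range(n_surrogates):
        surro = np.empty_like(ts.data)
        for i in range(n):
            for t in range(r):
                stream = streams[(s_idx * n + i) * r + t]
                try:
                    surro[i, :, t] = iaaft(
                        ts.data[i, :, t],
                        max_iter=max_iter,
                        tol=tol,
                        seed=np.random.default_rng(stream),
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"IAAFT failed for node {i} ({ts.labels[i]}), trial {t}: {exc}"
                    ) from exc
        null_ts = SourceTimeSeriesSet(surro, ts.fs, ts.epoch, list(ts.labels))
        env = band_envelopes(null_ts, bins, window)
        blocks = connectivity_blocks(env, trial_pooling=trial_pooling)
        if acc_sum is None:
            acc_sum = {(b.binA, b.binB): b.mat.copy() for b in blocks}
            acc_sq = {(b.binA, b.binB): b.mat**2 for b in blocks}
        else:
            for b in blocks:
                acc_sum[(b.binA, b.binB)] += b.mat
                acc_sq[(b.binA, b.binB)] += b.mat**2

    mean = {k: v / n_surrogates for k, v in acc_sum.items()}
    sd = {}
    for k in acc_sum:
        var = (acc_sq[k] - n_surrogates * mean[k] ** 2) / (n_surrogates - 1)
        sd[k] = np.sqrt(np.clip(var, 0.0, None))
    return NullStats(mean=mean, sd=sd, n_surrogates=n_surrogates)


def zscore_blocks(
    empirical: list[ConnectivityBlock], null: NullStats
) -> list[ConnectivityBlock]:
    """z-score empirical blocks against the surrogate null.

    ``z = (emp - mean_null) / sd_null``; connections with a degenerate
    null (sd = 0) are set to z = 0 and logged rather than allowed to
    blow up — a connection the null cannot vary should never become an
    edge, let alone a hub.
    """
    out = []
    for b in empirical:
        key = (b.binA, b.binB)
        if key not in null.mean:
            raise ValueError(f"null statistics missing for block {key}")
        mu, sd = null.mean[key], null.sd[key]
        if mu.shape != b.mat.shape:
            raise ValueError(
                f"shape mismatch in block {key}: empirical {b.mat.shape} "
                f"vs null {mu.shape}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (b.mat - mu) / sd
        degenerate = sd == 0
        if b.binA == b.binB:
            degenerate = degenerate & ~np.eye(sd.shape[0], dtype=bool)
        if degenerate.any():
            logger.warning(
                "block %s: %d connection(s) with zero null sd set to z=0",
                key,
                int(degenerate.sum()),
            )
        z = np.where(sd == 0, 0.0, z)
        if b.binA == b.binB:
            np.fill_diagonal(z, 0.0)
        out.append(ConnectivityBlock(b.binA, b.binB, z))
    return out
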