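"""Filtering, orthogonalization, envelopes and AAC blocks."""

import numpy as np
import pytest
from scipy import signal as sps

from dcinet import (
    ConnectivityBlock,
    FrequencyBin,
    SourceTimeSeriesSet,
    aac,
    band_envelopes,
    connectivity_blocks,
    make_bins,
    preprocess_broadband,
    symmetric_orthogonalize,
    symmetrize_max,
)


def _ts(data, fs, t0=0.0):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    t1 = t0 + data.shape[1] / fs
    return SourceTimeSeriesSet(data, fs, (t0, t1), [f"n{i}" for i in range(data.shape[0])])


class TestPreprocess:
    fs = 400.0

    # the 0.1 Hz high-pass settles over tens of seconds, so these run on
    # long recordings and evaluate away from the edges (as in practice,
    # where broadband filtering precedes epoching)
    def test_notch_removes_line_frequency(self):
        t = np.arange(int(40 * self.fs)) / self.fs
        ts = _ts([np.sin(2 * np.pi * 60 * t)], self.fs)
        out = preprocess_broadband(ts, band=(0.1, 100), notch=60)
        core = out.data[0, int(10 * self.fs):-int(10 * self.fs), 0]
        assert np.sqrt((core**2).mean()) < 0.1 * np.sqrt(0.5)

    def test_passband_amplitude_preserved(self):
        t = np.arange(int(40 * self.fs)) / self.fs
        ts = _ts([np.sin(2 * np.pi * 10 * t)], self.fs)
        out = preprocess_broadband(ts, band=(0.1, 100), notch=60)
        core = out.data[0, int(10 * self.fs):-int(10 * self.fs), 0]
        assert abs(np.abs(core).max() - 1.0) < 0.05

    def test_stopband_attenuation_20db(self, rng):
        ts = _ts([rng.standard_normal(int(8 * self.fs))], self.fs)
        out = preprocess_broadband(ts, band=(0.1, 100), notch=None)
        f, p = sps.welch(out.data[0, :, 0], fs=self.fs, nperseg=1024)
        passband = p[(f > 20) & (f < 80)].mean()
        stopband = p[f > 130].mean()
        assert 10 * np.log10(passband / stopband) >= 20

    def test_band_beyond_nyquist_raises(self):
        ts = _ts([np.zeros(100) + np.arange(100)], 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_broadband(ts, band=(0.1, 60), notch=None)


class TestOrthogonalize:
    def test_already_orthogonal_is_fixed_point(self):
        fs = 100.0
        t = np.arange(200) / fs
        rows = np.array([np.sin(2 * np.pi * k * t) for k in (1, 2, 3)])  # orthogonal
        out = symmetric_orthogonalize(_ts(rows, fs))
        assert np.max(np.abs(out.data[:, :, 0] - rows)) < 1e-8

    def test_output_gram_is_diagonal(self, rng):
        x = rng.standard_normal((4, 300, 2))
        out = symmetric_orthogonalize(_ts(x, 100.0))
        flat = out.data.reshape(4, -1)
        gram = flat @ flat.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(gram))

    def test_rank_deficient_raises(self):
        x = np.ones((3, 2))  # 3 nodes, 2 samples: rank-deficient
        ts = SourceTimeSeriesSet(x[:, :, None], 1.0, (0.0, 2.0), ["a", "b", "c"])
        with pytest.raises(ValueError):
            symmetric_orthogonalize(ts)

    def test_close_to_input(self, rng):
        """The orthogonal set stays near the input for nearly orthogonal data."""
        fs = 100.0
        t = np.arange(500) / fs
        rows = np.array([np.sin(2 * np.pi * k * t) for k in (2, 5, 9)])
        perturbed = rows + 0.01 * rng.standard_normal(rows.shape)
        out = symmetric_orthogonalize(_ts(perturbed, fs))
        rel = np.linalg.norm(out.data[:, :, 0] - perturbed) / np.linalg.norm(perturbed)
        assert rel < 0.05


class TestMakeBins:
    def test_study_layout(self):
        bins = make_bins(0.5, 50.5, 5)
        assert len(bins) == 10
        assert (bins[0].low_hz, bins[0].high_hz) == (0.5, 5.5)
        assert (bins[-1].low_hz, bins[-1].high_hz) == (45.5, 50.5)
        # contiguous, non-overlapping
        for a, b in zip(bins, bins[1:]):
            assert a.high_hz == b.low_hz

    def test_simple_split(self):
        bins = make_bins(0, 10, 5)
        assert [(b.low_hz, b.high_hz) for b in bins] == [(0, 5), (5, 10)]

    def test_indivisible_range_raises(self):
        with pytest.raises(ValueError, match="integer number"):
            make_bins(0, 7, 5)


class TestEnvelopes:
    fs = 200.0

    def _sine_ts(self, freq, amp=None, seconds=3.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        a = amp(t) if callable(amp) else 1.0
        return _ts([a * np.sin(2 * np.pi * freq * t)], self.fs), t

    def test_unit_sine_recovers_unit_envelope(self):
        bins = [FrequencyBin(8, 12)]
        ts, _ = self._sine_ts(10.0)
        env = band_envelopes(ts, bins, (0.8, 1.3))
        assert np.max(np.abs(env.envelopes[0] - 1.0)) < 0.05

    def test_am_modulator_recovered(self):
        bins = [FrequencyBin(15, 25)]
        amp = lambda t: 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        ts, t = self._sine_ts(20.0, amp=amp)
        env = band_envelopes(ts, bins, (0.8, 1.3))
        i0, i1 = int(0.8 * self.fs), int(1.3 * self.fs)
        target = amp(t)[i0:i1]
        rel_rms = np.sqrt(((env.envelopes[0][0, :, 0] - target) ** 2).mean()) / \
            np.sqrt((target**2).mean())
        assert rel_rms < 0.05

    def test_zero_signal_zero_envelope(self):
        ts = _ts([np.zeros(600)], self.fs)
        env = band_envelopes(ts, [FrequencyBin(8, 12)], (0.8, 1.3))
        assert np.allclose(env.envelopes[0], 0.0)

    def test_window_outside_epoch_raises(self):
        ts = _ts([np.zeros(600) + np.sin(np.arange(600))], self.fs)
        with pytest.raises(ValueError, match="window"):
            band_envelopes(ts, [FrequencyBin(8, 12)], (2.5, 3.5))


class TestAAC:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert aac(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert aac(x, 10 - 2 * x) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r = 10 / sqrt(10 * 14.8) from the textbook sums
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        assert aac(x, y) == pytest.approx(10 / np.sqrt(148), abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.random(50), rng.random(50)
        assert aac(x, y) == pytest.approx(aac(y, x), abs=1e-14)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            aac(np.ones(10), np.arange(10.0))


class TestConnectivityBlocks:
    @pytest.mark.parametrize(
        "n_bins,expected", [(1, 1), (4, 10), (10, 55)]
    )
    def test_block_count(self, n_bins, expected, rng):
        from dcinet import EnvelopeSet

        bins = [FrequencyBin(2 + 4 * k, 6 + 4 * k) for k in range(n_bins)]
        envs = [np.abs(rng.standard_normal((3, 40, 2))) for _ in bins]
        env = EnvelopeSet(envs, bins, (0.8, 1.3), 64.0, ["a", "b", "c"])
        blocks = connectivity_blocks(env)
        assert len(blocks) == expected
        n_within = sum(b.kind == "within" for b in blocks)
        assert n_within == n_bins

    def test_within_blocks_symmetric_with_zero_diagonal(self, noise_ts, small_bins):
        env = band_envelopes(noise_ts, small_bins, (0.8, 1.3))
        for b in connectivity_blocks(env):
            if b.kind == "within":
                assert np.allclose(b.mat, b.mat.T)
                assert np.all(np.diag(b.mat) == 0)

    def test_between_block_orientation(self, small_bins):
        """Entry [i, j] couples node i's low-bin to node j's high-bin envelope."""
        from dcinet import EnvelopeSet

        rng = np.random.default_rng(3)
        lo = np.abs(rng.standard_normal((3, 60, 1)))
        hi = np.abs(rng.standard_normal((3, 60, 1)))
        hi[2, :, 0] = lo[0, :, 0]  # plant: node0-low == node2-high
        env = EnvelopeSet([lo, hi], small_bins, (0.8, 1.3), 64.0, ["a", "b", "c"])
        between = [b for b in connectivity_blocks(env) if b.kind == "between"][0]
        assert between.mat[0, 2] == pytest.approx(1.0)
        assert between.mat[2, 0] < 0.99

    def test_node_permutation_equivariance(self, noise_ts, small_bins):
        env = band_envelopes(noise_ts, small_bins, (0.8, 1.3))
        blocks = connectivity_blocks(env)
        perm = np.array([2, 0, 4, 1, 3])
        ts_p = SourceTimeSeriesSet(
            noise_ts.data[perm], noise_ts.fs, noise_ts.epoch,
            [noise_ts.labels[i] for i in perm],
        )
        blocks_p = connectivity_blocks(band_envelopes(ts_p, small_bins, (0.8, 1.3)))
        for b, bp in zip(blocks, blocks_p):
            assert np.allclose(bp.mat, b.mat[np.ix_(perm, perm)], atol=1e-10)


class TestPlantedPairDetection:
    def test_single_planted_pair_attains_block_maximum(self):
        """With adequate power (20 trials, oscillation twice the noise sd),
        a strength-0.9 planted coupling is the largest entry of its block
        in >= 95% of 20 seeds."""
        from dcinet import SynthConfig, generate_coupled_timeseries

        bins = make_bins(2.0, 18.0, 8.0)
        wins = 0
        for seed in range(20):
            cfg = SynthConfig(
                n_nodes=8, n_trials=20, fs=64.0, epoch=(0.0, 2.0), bins=bins,
                planted_pairs=[(0, 1, 0, 1, 0.9)], seed=seed, oscillation_amp=2.0,
            )
            ts = generate_coupled_timeseries(cfg)
            env = band_envelopes(ts, bins, (0.8, 1.3))
            between = next(
                b for b in connectivity_blocks(env) if b.kind == "between"
            )
            wins += int(between.mat[0, 1] == between.mat.max())
        assert wins >= 19


class TestSymmetrizeMax:
    def test_definition(self):
        blk = ConnectivityBlock(0, 1, np.array([[0, 0.3], [0.7, 0]]))
        out = symmetrize_max(blk)
        assert np.array_equal(out.mat, [[0, 0.7], [0.7, 0]])

    def test_symmetric_fixed_point(self, rng):
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        blk = ConnectivityBlock(0, 1, m)
        assert np.array_equal(symmetrize_max(blk).mat, m)

    def test_zero_preserved(self):
        blk = ConnectivityBlock(0, 0, np.zeros((3, 3)))
        assert np.array_equal(symmetrize_max(blk).mat, np.zeros((3, 3)))
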