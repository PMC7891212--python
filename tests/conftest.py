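import numpy as np
import pytest

from dcinet import (
    FrequencyBin,
    SourceTimeSeriesSet,
    SupraAdjacency,
    SynthConfig,
    generate_coupled_timeseries,
    make_bins,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bins():
    """Two wide bins that fit a low sampling rate (cheap tests)."""
    return make_bins(2.0, 18.0, 8.0)


@pytest.fixture
def noise_ts(small_bins):
    """Five independent-noise nodes: no coupling anywhere."""
    cfg = SynthConfig(
        n_nodes=5, n_trials=3, fs=64.0, epoch=(0.0, 2.0),
        bins=small_bins, planted_pairs=[], seed=7,
    )
    return generate_coupled_timeseries(cfg)


@pytest.fixture
def toy_supra():
    """N=3, B=2 supra with 3 interlayer edges, 2 incident to node 1.

    Within layers: a path 0-1-2 in each layer.  Interlayer block (0,1)
    has nonzeros at (0,0) — a replica self-pair — plus (0,1) and (1,2);
    two of the three interlayer edges touch node 1.
    """
    N, B = 3, 2
    intra = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
    between = np.zeros((N, N))
    between[0, 0] = 0.8
    between[0, 1] = 0.6
    between[1, 2] = 0.4
    mat = np.zeros((N * B, N * B))
    mat[:N, :N] = intra
    mat[N:, N:] = intra
    mat[:N, N:] = between
    mat[N:, :N] = between.T
    return SupraAdjacency(n_nodes=N, n_layers=B, mat=mat)


def random_supra(n_nodes, n_layers, rng, density=0.3):
    """Random symmetric supra-adjacency for oracle checks."""
    nb = n_nodes * n_layers
    w = rng.random((nb, nb))
    w = np.where(rng.random((nb, nb)) < density, w, 0.0)
    w = np.triu(w, k=1)
    w = w + w.T
    return SupraAdjacency(n_nodes=n_nodes, n_layers=n_layers, mat=w)
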