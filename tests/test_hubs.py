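"""Versatility, hub detection, interconnectedness, DCI and group inference."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dcinet import (
    SupraAdjacency,
    dci,
    dci_profile,
    detect_hubs,
    generate_multilayer_fixture,
    group_test,
    interconnectedness,
    versatility,
    zscore_nodes,
)
from conftest import random_supra


class TestVersatility:
    def test_single_layer_ring_is_uniform(self):
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        v = versatility(SupraAdjacency(n, 1, w))
        assert np.allclose(v, 1 / n, atol=1e-9)

    def test_aggregated_scores_sum_to_one(self, rng):
        sup = random_supra(6, 3, rng)
        assert versatility(sup).sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_layer_equals_networkx_pagerank(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        w = rng.random((n, n))
        w[w < 0.5] = 0
        w = np.triu(w, 1)
        w = w + w.T
        if not w.any():
            pytest.skip("empty draw")
        v = versatility(SupraAdjacency(n, 1, w), tol=1e-14)
        pr = nx.pagerank(
            nx.from_numpy_array(w), alpha=0.85, tol=1e-14, max_iter=5000,
            weight="weight",
        )
        assert max(abs(v[i] - pr[i]) for i in range(n)) < 1e-8

    def test_duplicated_coupled_layers_preserve_single_layer_ranking(self):
        rng = np.random.default_rng(2)
        n = 8
        w = rng.random((n, n))
        w = np.triu(w, 1)
        w = w + w.T
        single = versatility(SupraAdjacency(n, 1, w), tol=1e-13)
        supra = np.zeros((2 * n, 2 * n))
        supra[:n, :n] = w
        supra[n:, n:] = w
        supra[:n, n:] = np.eye(n) * 0.5  # identity replica coupling
        supra[n:, :n] = np.eye(n) * 0.5
        double = versatility(SupraAdjacency(n, 2, supra), tol=1e-13)
        assert np.array_equal(np.argsort(single), np.argsort(double))

    def test_all_zero_supra_raises(self):
        sup = SupraAdjacency(3, 2, np.zeros((6, 6)))
        with pytest.raises(ValueError, match="all-zero"):
            versatility(sup)


class TestZScoreAndDetection:
    def test_hand_arithmetic_population_sd(self):
        z = zscore_nodes(np.array([1.0, 2.0, 3.0]))
        sd = np.sqrt(2 / 3)  # population convention
        assert np.allclose(z, [-1 / sd, 0, 1 / sd])

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_nodes(np.ones(5))

    def test_idempotent_on_standardized_input(self, rng):
        x = zscore_nodes(rng.random(20))
        assert np.allclose(zscore_nodes(x), x, atol=1e-12)

    def test_strict_threshold(self):
        flags = detect_hubs(np.array([2.5, 1.0, -0.5]), threshold=2)
        assert flags.tolist() == [True, False, False]
        assert detect_hubs(np.array([2.0, 0.0]), threshold=2).tolist() == [False, False]


class TestInterconnectedness:
    def test_block_diagonal_is_zero(self, rng):
        n, b = 4, 3
        sup = np.zeros((n * b, n * b))
        for a in range(b):
            w = rng.random((n, n))
            w = np.triu(w, 1)
            sup[a * n:(a + 1) * n, a * n:(a + 1) * n] = w + w.T
        assert interconnectedness(SupraAdjacency(n, b, sup)) == 0

    def test_hand_counted_example(self, toy_supra):
        assert interconnectedness(toy_supra) == 3

    def test_complete_between_block_counts_replica_pairs(self):
        n = 4
        sup = np.zeros((2 * n, 2 * n))
        sup[:n, n:] = 1.0
        sup[n:, :n] = 1.0
        s = SupraAdjacency(n, 2, sup)
        assert interconnectedness(s) == n * n
        assert interconnectedness(s, count_replica_pairs=False) == n * n - n


class TestDCI:
    def test_node_without_interlayer_edges_scores_zero(self, toy_supra):
        # all three interlayer edges of toy_supra touch nodes 0, 1, 2;
        # build a 4th isolated-in-interlayer node by padding
        n, b = 4, 2
        sup = np.zeros((n * b, n * b))
        old = toy_supra.mat
        for a_ in range(2):
            for b_ in range(2):
                sup[a_ * n:a_ * n + 3, b_ * n:b_ * n + 3] = old[
                    a_ * 3:(a_ + 1) * 3, b_ * 3:(b_ + 1) * 3
                ]
        s = SupraAdjacency(n, b, sup)
        assert dci(s, 3) == 0.0

    def test_hand_counted_percent_change(self, toy_supra):
        # I_full = 3, two interlayer edges incident to node 1
        assert dci(toy_supra, 1) == pytest.approx(100 * 2 / 3, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rebuild_oracle(self, seed):
        """DCI by zeroing replicas equals a rebuild-from-scratch oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        b = int(rng.integers(2, 4))
        sup = random_supra(n, b, rng, density=0.25)
        if interconnectedness(sup) == 0:
            pytest.skip("no interlayer edges drawn")
        i_full = interconnectedness(sup)
        for node in range(n):
            keep = [i for i in range(n) if i != node]
            rebuilt = np.zeros(((n - 1) * b, (n - 1) * b))
            for a_ in range(b):
                for b_ in range(b):
                    blk = sup.block(a_, b_)[np.ix_(keep, keep)]
                    rebuilt[
                        a_ * (n - 1):(a_ + 1) * (n - 1),
                        b_ * (n - 1):(b_ + 1) * (n - 1),
                    ] = blk
            i_removed = interconnectedness(SupraAdjacency(n - 1, b, rebuilt))
            expected = 100 * (i_full - i_removed) / i_full
            assert dci(sup, node) == pytest.approx(expected, abs=1e-12)

    def test_zero_interconnectedness_raises(self, rng):
        n, b = 3, 2
        sup = np.zeros((n * b, n * b))
        sup[0, 1] = sup[1, 0] = 1.0  # intralayer only
        with pytest.raises(ValueError, match="undefined|zero"):
            dci(SupraAdjacency(n, b, sup), 0)


class TestDCIProfile:
    def test_all_zero_raw_stays_zero(self, toy_supra):
        # node 3 does not exist here; use candidates with zero DCI instead
        n, b = 4, 2
        sup = np.zeros((n * b, n * b))
        sup[0, n + 1] = sup[n + 1, 0] = 1.0  # one interlayer edge (nodes 0,1)
        s = SupraAdjacency(n, b, sup)
        prof = dci_profile(s, np.array([2, 3]))
        assert np.array_equal(prof.dci_raw, [0.0, 0.0])
        assert np.array_equal(prof.dci_scaled, [0.0, 0.0])

    def test_scaling_preserves_zeros_and_order(self):
        n, b = 4, 2
        rng = np.random.default_rng(1)
        sup = random_supra(n, b, rng, density=0.4)
        prof = dci_profile(sup, np.arange(n))
        zero_raw = prof.dci_raw == 0
        assert np.array_equal(prof.dci_scaled == 0, zero_raw)
        assert np.array_equal(np.argsort(prof.dci_raw), np.argsort(prof.dci_scaled))
        nonzero = prof.dci_raw != 0
        if nonzero.any():
            assert prof.dci_scaled[nonzero].std(ddof=0) <= 1.0 + 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_connector_hub_attains_top_rank(self, seed):
        sup = generate_multilayer_fixture(
            12, 3, intralayer_density=0.3, interlayer_density=0.08,
            planted_hub=4, seed=300 + seed,
        )
        prof = dci_profile(sup, np.arange(12))
        assert prof.candidates[np.argmax(prof.dci_scaled)] == 4


class TestGroupTest:
    def test_exact_p_for_twelve_concordant_subjects(self):
        values = np.ones((12, 1))
        res = group_test(values)
        assert res.exact
        assert res.p_value[0] == pytest.approx(1 / 4096, abs=1e-12)

    def test_symmetric_values_match_enumeration_oracle(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        res = group_test(x[:, None])
        count = 0
        for signs in itertools.product([-1, 1], repeat=6):
            if np.mean(np.array(signs) * x) >= x.mean() - 1e-12:
                count += 1
        assert res.p_value[0] == pytest.approx(count / 64, abs=1e-12)
        assert 0.3 < res.p_value[0] < 0.8

    def test_all_negative_values_give_large_p(self):
        values = -np.abs(np.random.default_rng(0).random((10, 1))) - 0.1
        res = group_test(values)
        assert res.p_value[0] >= 0.97

    def test_all_zero_node_flagged_with_p_one(self):
        values = np.zeros((5, 2))
        values[:, 1] = [1, 2, 1, 3, 2]
        res = group_test(values)
        assert res.p_value[0] == 1.0
        assert res.all_zero[0] and not res.all_zero[1]

    def test_monte_carlo_branch_reproducible(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((20, 3))  # 2^20 too large: MC branch
        a = group_test(values, n_permutations=500, seed=42)
        b = group_test(values, n_permutations=500, seed=42)
        assert not a.exact
        assert np.array_equal(a.p_value, b.p_value)
        assert np.all(a.p_value > 0)

    def test_type_one_error_calibrated_under_symmetric_null(self):
        """Nominal 5% rejection over 400 null node-tests (exact branch)."""
        rng = np.random.default_rng(99)
        rejections = []
        for _ in range(20):
            values = rng.standard_normal((12, 20))
            res = group_test(values)
            rejections.extend(res.p_value < 0.05)
        frac = np.mean(rejections)
        assert 0.02 <= frac <= 0.08

    def test_single_subject_raises(self):
        with pytest.raises(ValueError, match="two subjects"):
            group_test(np.ones((1, 3)))
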