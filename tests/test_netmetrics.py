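"""Centrality, node weights, primary nodes, strength/connectivity
metrics, sub-matrices, 3-node networks and autocorrelation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from coevnet import netmetrics
from coevnet.coevo import CoevolutionMatrix
from coevnet.netmetrics import (
    NetworkMetrics,
    NetworkSelection,
    PrimaryNode,
    centrality_autocorrelation,
    detect_primary_nodes,
    difference_profile,
    eigen_centrality,
    network_metrics,
    node_weights,
    submatrix,
    three_node_network,
)


def power_iteration(A, iters=10_000, tol=1e-14):
    """Independent leading-eigenpair oracle."""
    rng = np.random.default_rng(0)
    v = rng.random(A.shape[0]) + 0.1
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = A @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return np.full(A.shape[0], 1 / np.sqrt(A.shape[0])), 0.0
        w /= nrm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    lam = float(v @ A @ v)
    return v, lam


class TestEigenCentrality:
    def test_two_node_graph(self):
        c = eigen_centrality(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(c.E, [np.sqrt(0.5)] * 2)
        assert c.lam == pytest.approx(1.0)

    def test_path_graph(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        c = eigen_centrality(A)
        assert np.allclose(c.E, [0.5, np.sqrt(0.5), 0.5], atol=1e-10)
        assert c.lam == pytest.approx(np.sqrt(2))

    def test_scale_invariance_of_vector(self):
        rng = np.random.default_rng(4)
        A = np.abs(rng.normal(size=(8, 8)))
        A = (A + A.T) / 2
        c1 = eigen_centrality(A)
        c2 = eigen_centrality(7.5 * A)
        assert np.allclose(c1.E, c2.E, atol=1e-10)
        assert c2.lam == pytest.approx(7.5 * c1.lam)

    def test_all_zero_matrix_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            c = eigen_centrality(np.zeros((5, 5)))
        assert np.allclose(c.E, 1 / np.sqrt(5))
        assert c.lam == 0.0

    def test_against_power_iteration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            A = np.abs(rng.normal(size=(20, 20)))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            c = eigen_centrality(A)
            v, lam = power_iteration(A)
            v = np.abs(v)
            assert np.allclose(c.E, v, atol=1e-8)
            assert c.lam == pytest.approx(lam, abs=1e-8)

    def test_unit_norm_and_nonnegative(self, reference_fit):
        res, _ = reference_fit
        assert np.linalg.norm(res.centrality.E) == pytest.approx(1.0)
        assert (res.centrality.E >= 0).all()


class TestNodeWeights:
    def test_uniform_profile(self):
        prof = node_weights(np.full(20, 0.1), n=6)
        assert np.allclose(prof.W, 0.1)
        assert prof.W.size == 15

    def test_spike_spreads_over_windows(self):
        E = np.zeros(12)
        E[3] = 6 * 0.05
        prof = node_weights(E, n=6)
        covered = prof.W[max(0, 3 - 5):4]
        assert np.allclose(covered, 0.05)

    def test_window_one_is_identity(self):
        E = np.arange(5, dtype=float)
        assert np.allclose(node_weights(E, n=1).W, E)

    def test_window_longer_than_profile_rejected(self):
        with pytest.raises(ValueError):
            node_weights(np.zeros(4), n=6)


class TestDifferenceProfile:
    def test_proportional_profiles_cancel(self, stub_null_factory):
        ER = np.linspace(0.1, 0.5, 10)
        cp = netmetrics.CentralityProfile(E=2 * ER, lam=1.0)
        prof = difference_profile(cp, stub_null_factory(E_R=ER))
        assert np.allclose(prof.deltaW, 0.0, atol=1e-15)
        assert prof.scale == pytest.approx(2.0)

    def test_spike_hand_arithmetic(self, stub_null_factory):
        ER = np.full(5, 0.2)
        E = ER.copy()
        E[2] += 0.1
        cp = netmetrics.CentralityProfile(E=E, lam=1.0)
        prof = difference_profile(cp, stub_null_factory(E_R=ER), n=2)
        # scale = mean(E)/mean(E_R) = 0.22/0.2 = 1.1; deltaW = E - 0.22
        assert prof.scale == pytest.approx(1.1)
        assert np.allclose(prof.deltaW, [-0.02, -0.02, 0.08, -0.02, -0.02])
        assert prof.deltaW[2] > 0
        assert abs(prof.deltaW.mean()) < 1e-9

    def test_equal_profiles_give_unit_scale(self, stub_null_factory):
        ER = np.linspace(0.1, 0.3, 8)
        cp = netmetrics.CentralityProfile(E=ER.copy(), lam=1.0)
        prof = difference_profile(cp, stub_null_factory(E_R=ER))
        assert prof.scale == pytest.approx(1.0)
        assert np.allclose(prof.deltaW, 0.0, atol=1e-15)

    def test_zero_null_mean_rejected(self, stub_null_factory):
        cp = netmetrics.CentralityProfile(E=np.ones(4), lam=1.0)
        with pytest.raises(ValueError):
            difference_profile(cp, stub_null_factory(E_R=np.zeros(4)))


class TestDetectPrimaryNodes:
    def _profile(self, deltaW, n=6):
        prof = netmetrics.NodeWeightProfile(n=n, deltaW=np.asarray(deltaW))
        prof.W = np.convolve(prof.deltaW, np.ones(n) / n, mode="valid")
        return prof

    def test_flat_profile_has_no_nodes(self, stub_null_factory):
        prof = self._profile(np.zeros(30))
        null = stub_null_factory(window=(0.0, 1e-3))
        assert detect_primary_nodes(prof, null) == []

    def test_single_planted_segment_detected(self, stub_null_factory):
        dW = np.zeros(40)
        dW[12:18] = 5e-3  # 5 sigma of the stub window sigma
        prof = self._profile(dW)
        nodes = detect_primary_nodes(prof, stub_null_factory(window=(0.0, 1e-3)))
        assert len(nodes) == 1
        assert 13 <= nodes[0].peak <= 18  # 1-based

    def test_two_separated_segments_give_two_nodes(self, stub_null_factory):
        dW = np.zeros(60)
        dW[10:16] = 5e-3
        dW[40:46] = 5e-3
        prof = self._profile(dW)
        nodes = detect_primary_nodes(prof, stub_null_factory(window=(0.0, 1e-3)))
        assert len(nodes) == 2
        assert 11 <= nodes[0].peak <= 16
        assert 41 <= nodes[1].peak <= 46

    def test_planted_segments_recovered_in_reference_fit(self, reference_fit):
        res, truth = reference_fit
        peaks = [nd.peak for nd in res.primary_nodes]
        for (a, b) in truth.node_segments:
            assert any(a - 2 <= p <= b + 2 for p in peaks)


class TestNetworkMetrics:
    RAND_M = NetworkMetrics(label="rand", sum_pos=17621.4, n_corr=116900,
                            n_pos=53348, n_matrix=152100)
    RAND_G = NetworkMetrics(label="rand", sum_pos=11423.3, n_corr=76887,
                            n_pos=34532, n_matrix=103041)

    def test_intra_domain_strength_and_connectivity(self):
        m = NetworkMetrics.from_aggregates(9776.6, 24142, 16538, 33124,
                                           null_ref=self.RAND_M)
        assert round(m.S_M, 2) == 1.79
        assert round(m.C, 2) == 0.95

    def test_motor_subdomain_strength(self):
        m = NetworkMetrics.from_aggregates(832.5, 2300, 1466, 3969,
                                           null_ref=self.RAND_G)
        assert round(m.S_M, 2) == 1.72
        assert round(m.C, 2) == 0.78

    def test_self_normalisation_is_unity(self):
        m = NetworkMetrics.from_aggregates(
            17621.4, 116900, 53348, 152100, null_ref=self.RAND_M)
        assert m.S_M == pytest.approx(1.0)
        assert m.C == pytest.approx(1.0)

    def test_no_positive_entries_warns(self):
        V = -np.ones((4, 4))
        D = CoevolutionMatrix(values=V)
        sel = NetworkSelection.intra(range(4))
        with pytest.warns(UserWarning, match="S_M=0"):
            m = network_metrics(D, sel, self.RAND_M)
        assert m.S_M == 0.0

    def test_symmetric_counting_convention(self):
        V = np.zeros((4, 4))
        V[0, 1] = V[1, 0] = 2.0
        V[2, 3] = V[3, 2] = -1.0
        D = CoevolutionMatrix(values=V)
        m = network_metrics(D, NetworkSelection.intra(range(4)))
        assert m.n_matrix == 16
        assert m.n_corr == 12       # off-diagonal entries, both triangles
        assert m.n_pos == 2         # (0,1) and (1,0)
        assert m.sum_pos == pytest.approx(4.0)

    def test_counts_ordering_invariant(self):
        assert NetworkMetrics(label="", sum_pos=1, n_corr=5, n_pos=3,
                              n_matrix=9).density == pytest.approx(5 / 9)


class TestSubmatrix:
    def test_full_range_is_identity(self, reference_fit):
        res, _ = reference_fit
        block, sel = submatrix(res.matrix, range(res.matrix.L),
                               range(res.matrix.L))
        assert np.allclose(np.nan_to_num(block.values),
                           np.nan_to_num(res.matrix.values))

    def test_rectangular_block_count(self):
        V = np.random.default_rng(0).random((10, 10))
        V = (V + V.T) / 2
        D = CoevolutionMatrix(values=V)
        _block, sel = submatrix(D, range(4), range(4, 10))
        assert sel.n_matrix == 24

    def test_out_of_range_rejected(self, reference_fit):
        res, _ = reference_fit
        with pytest.raises(IndexError):
            submatrix(res.matrix, [0, 1], [res.matrix.L])

    def test_block_centrality_matches_standalone(self):
        """With no inter-block signal, a domain's centrality inside the
        composite matrix matches centrality on the domain alone."""
        rng = np.random.default_rng(8)
        A = np.abs(rng.normal(size=(12, 12)))
        A = (A + A.T) / 2
        V = np.zeros((20, 20))
        V[:12, :12] = A
        D = CoevolutionMatrix(values=V)
        block, _ = submatrix(D, range(12), range(12))
        c_block = eigen_centrality(block)
        c_alone = eigen_centrality(CoevolutionMatrix(values=A.copy()))
        rho, _ = spearmanr(c_block.E, c_alone.E)
        assert rho > 0.999


class TestThreeNodeNetwork:
    def _nodes(self):
        return [
            PrimaryNode(start=1, end=6, peak=3, weight=0.3),
            PrimaryNode(start=21, end=26, peak=23, weight=0.2),
            PrimaryNode(start=41, end=46, peak=43, weight=0.1),
        ]

    def test_pairwise_union_block_convention(self):
        """Three disjoint 6-windows: n_matrix = 3 x (6+6)^2 = 432 and
        n_corr = 3 x (144 - 12) = 396 on a fully defined matrix."""
        V = np.random.default_rng(1).random((60, 60))
        V = (V + V.T) / 2
        D = CoevolutionMatrix(values=V)
        m = three_node_network(D, self._nodes())
        assert m.n_matrix == 432
        assert m.n_corr == 396

    def test_printed_three_node_row(self):
        rand = NetworkMetrics(label="rand", sum_pos=11423.3, n_corr=76887,
                              n_pos=34532, n_matrix=103041)
        m = NetworkMetrics.from_aggregates(102.3, 264, 148, 432,
                                           null_ref=rand)
        assert round(m.S_M, 2) == 2.09

    def test_fewer_than_three_nodes_rejected(self):
        V = np.ones((30, 30))
        D = CoevolutionMatrix(values=V)
        with pytest.raises(ValueError, match="primary nodes"):
            three_node_network(D, self._nodes()[:2])

    def test_zero_positive_correlations_warns(self):
        V = -np.ones((60, 60))
        D = CoevolutionMatrix(values=V)
        rand = NetworkMetrics(label="rand", sum_pos=100.0, n_corr=396,
                              n_pos=200, n_matrix=432)
        with pytest.warns(UserWarning, match="S_M=0"):
            m = three_node_network(D, self._nodes(), rand)
        assert m.S_M == 0.0


class TestAutocorrelation:
    def test_periodic_profile_peaks_at_period(self):
        x = np.sin(2 * np.pi * np.arange(70) / 7)
        lags, G, peaks = centrality_autocorrelation(x, max_lag=20)
        assert 7 in peaks
        assert 14 in peaks

    def test_white_noise_stays_small(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=900)
        _lags, G, _ = centrality_autocorrelation(x, max_lag=30)
        assert np.abs(G).max() < 3 / np.sqrt(x.size)

    def test_constant_profile_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            _l, G, peaks = centrality_autocorrelation(np.ones(30), max_lag=5)
        assert np.allclose(G, 0.0)
        assert peaks == []

    def test_helical_repeat_in_reference_profile(self, reference_fit):
        res, _ = reference_fit
        lags, G, peaks = res.autocorrelation(max_lag=30)
        assert lags.size == 30
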