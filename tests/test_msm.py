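"""MSM estimation: counting, trimming, ML estimation, implied timescales,
lag scans, GMRQ cross-validation and bootstrap, against closed forms and
independent solvers."""

import numpy as np
import pytest

from helixmsm.msm import (CountMatrix, bootstrap_models, count_transitions,
                          estimate_T, fit_msm, gmrq_cross_validate,
                          implied_timescales, lag_scan,
                          largest_connected_set)


def sample_chain(T, n, seed, start=0):
    rng = np.random.default_rng(seed)
    k = T.shape[0]
    out = np.empty(n, dtype=np.intp)
    state = start
    for t in range(n):
        out[t] = state
        state = rng.choice(k, p=T[state])
    return out


class TestCountTransitions:
    def test_self_transitions(self):
        cm = count_transitions([np.array([0, 0, 0, 0])], 1)
        assert cm.counts[0, 0] == 3

    def test_alternating_sequence(self):
        cm = count_transitions([np.array([0, 1, 0, 1, 0])], 1)
        assert cm.counts[0, 1] == 2
        assert cm.counts[1, 0] == 2
        assert cm.counts.sum() == 4

    def test_lag_two_pairs_enumerated_by_hand(self):
        # [0,1,0,1,0] at lag 2: pairs (0,0),(1,1),(0,0) -> c00=2, c11=1
        cm = count_transitions([np.array([0, 1, 0, 1, 0])], 2)
        assert cm.counts[0, 0] == 2
        assert cm.counts[1, 1] == 1
        assert cm.counts.sum() == 3

    def test_no_cross_trajectory_pairs(self):
        cm = count_transitions([np.array([0, 0]), np.array([1, 1])], 1)
        assert cm.counts[0, 1] == 0 and cm.counts[1, 0] == 0

    def test_all_too_short_errors(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions([np.array([0, 1])], 5)


class TestLargestConnectedSet:
    def test_fully_connected_identity(self):
        cm = CountMatrix(np.array([[3, 2], [1, 4]]), 1, 1.0)
        active, trimmed = largest_connected_set(cm)
        np.testing.assert_array_equal(active, [0, 1])
        np.testing.assert_array_equal(trimmed.counts, cm.counts)

    def test_absorbing_state_excluded(self):
        # state 2 receives counts but never exits
        counts = np.array([[5, 3, 1], [2, 5, 0], [0, 0, 0]])
        active, trimmed = largest_connected_set(CountMatrix(counts, 1, 1.0))
        np.testing.assert_array_equal(active, [0, 1])

    def test_matches_networkx_scc_oracle(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = (rng.random((6, 6)) < 0.25).astype(int) * \
                rng.integers(1, 10, size=(6, 6))
            if counts.sum() == 0:
                continue
            g = nx.DiGraph()
            g.add_nodes_from(range(6))
            for i in range(6):
                for j in range(6):
                    if counts[i, j] > 0:
                        g.add_edge(i, j)
            best, weight = None, -1
            for comp in nx.strongly_connected_components(g):
                m = sorted(comp)
                w = counts[np.ix_(m, m)].sum()
                if w > weight:
                    best, weight = m, w
            if weight == 0:
                # every strongly connected component is transition-free:
                # no stationary distribution exists
                with pytest.raises(ValueError):
                    largest_connected_set(CountMatrix(counts, 1, 1.0))
                continue
            active, _ = largest_connected_set(CountMatrix(counts, 1, 1.0))
            assert sorted(active.tolist()) == best


class TestEstimateT:
    def test_symmetric_counts(self):
        cm = CountMatrix(np.array([[9, 1], [1, 9]]), 1, 1.0)
        model = estimate_T(cm)
        np.testing.assert_allclose(model.T, [[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(model.pi, [0.5, 0.5], atol=1e-12)

    def test_row_normalization(self):
        cm = CountMatrix(np.array([[0, 4], [2, 2]]), 1, 1.0)
        model = estimate_T(cm)
        np.testing.assert_allclose(model.T, [[0.0, 1.0], [0.5, 0.5]])

    def test_stationary_matches_power_iteration(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            counts = rng.integers(1, 20, size=(5, 5))
            model = estimate_T(CountMatrix(counts, 1, 1.0))
            pi = np.full(5, 0.2)
            for _ in range(20000):
                pi = pi @ model.T
            pi /= pi.sum()
            np.testing.assert_allclose(model.pi, pi, atol=1e-10)
            np.testing.assert_allclose(model.pi @ model.T, model.pi,
                                       atol=1e-10)
            np.testing.assert_allclose(model.T.sum(axis=1), 1.0, atol=1e-10)

    def test_reversible_mode_detailed_balance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, size=(6, 6))
        model = estimate_T(CountMatrix(counts, 1, 1.0), reversible=True)
        flux = model.pi[:, None] * model.T
        np.testing.assert_allclose(flux, flux.T, atol=1e-10)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        cm = CountMatrix(np.array([[9, 1], [1, 9]]), 1, 1.0)
        model = estimate_T(cm)
        ts = implied_timescales(model)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.8), abs=1e-10)
        assert ts[0] == pytest.approx(4.4814, abs=1e-3)

    def test_identity_matrix_no_finite_timescales(self):
        cm = CountMatrix(np.eye(3, dtype=int) * 5, 1, 1.0)
        model = estimate_T(cm)
        assert implied_timescales(model).size == 0

    def test_negative_eigenvalues_excluded(self):
        # deterministic alternation: lam = -1
        cm = CountMatrix(np.array([[0, 9], [9, 0]]), 1, 1.0)
        model = estimate_T(cm)
        assert implied_timescales(model).size == 0

    def test_matches_independent_eigensolver(self):
        import scipy.linalg
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(4, 4))
        counts = counts + counts.T  # reversible-ish, real spectrum
        model = estimate_T(CountMatrix(counts, 2, 2.0), reversible=True)
        lam = np.sort(scipy.linalg.eigvals(model.T).real)[::-1]
        expected = -2.0 / np.log(lam[1:][lam[1:] > 0])
        np.testing.assert_allclose(
            implied_timescales(model), np.sort(expected)[::-1], atol=1e-8)


class TestLagScan:
    def test_markovian_chain_flat_timescales(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        seqs = [sample_chain(T, 20000, seed=s) for s in range(4)]
        table = lag_scan(seqs, [1, 2, 5, 10], frame_dt=1.0, n_timescales=1)
        t_true = -1.0 / np.log(0.9)
        assert np.nanmax(np.abs(table["t_1"] - t_true) / t_true) < 0.2

    def test_lumped_chain_timescale_rises_toward_truth(self):
        """Lumping a 4-state chain to 2 observed symbols biases the implied
        timescale down at short lags; it recovers as the lag grows."""
        # blocks {0,1} and {2,3} exchange only through gateway states 1 and
        # 2, so the lumped 2-symbol process has memory at short lags
        eps, fast = 0.05, 0.1
        T = np.array([
            [1 - fast, fast, 0.0, 0.0],
            [fast, 1 - fast - eps, eps, 0.0],
            [0.0, eps, 1 - fast - eps, fast],
            [0.0, 0.0, fast, 1 - fast],
        ])
        lam2 = np.sort(np.linalg.eigvals(T).real)[::-1][1]
        t_true = -1.0 / np.log(lam2)
        seqs = [sample_chain(T, 60000, seed=s) // 2 for s in range(3)]
        table = lag_scan(seqs, [1, 30], frame_dt=1.0, n_timescales=1)
        t_short, t_long = table["t_1"].to_numpy()
        assert t_short < t_long
        assert abs(t_long - t_true) / t_true < 0.25

    def test_single_lag_single_row(self):
        seqs = [np.array([0, 1, 0, 1, 0, 0, 1])]
        table = lag_scan(seqs, [1], frame_dt=0.5)
        assert len(table) == 1
        assert table["lag_time"].iloc[0] == 0.5


class TestGMRQ:
    def _two_state_projections(self, p=0.05, n=8000, n_traj=6, seed=0):
        T = np.array([[1 - p, p], [p, 1 - p]])
        rng = np.random.default_rng(seed)
        trajs = []
        for s in range(n_traj):
            labels = sample_chain(T, n, seed=seed + s, start=s % 2)
            x = np.where(labels == 1, 1.5, -1.5) + rng.normal(
                scale=0.1, size=n)
            trajs.append(x[:, None])
        return trajs, 1 - 2 * p

    def test_two_well_score_is_one_plus_lambda2(self):
        trajs, lam2 = self._two_state_projections()
        res = gmrq_cross_validate(trajs, [2], lag_frames=1, n_folds=3,
                                  n_timescales=1, seed=0)
        assert res.selected_k == 2
        assert np.nanmean(res.test_scores) == pytest.approx(1 + lam2,
                                                            abs=0.05)

    def test_k_one_scores_exactly_one(self):
        trajs, _ = self._two_state_projections(n=2000, n_traj=3)
        res = gmrq_cross_validate(trajs, [1], lag_frames=1, n_folds=3,
                                  n_timescales=1, seed=0)
        np.testing.assert_allclose(res.test_scores, 1.0, atol=1e-9)

    def test_resubstitution_score_non_decreasing_from_k1(self):
        """The variational bound: any extra state can only add non-negative
        Rayleigh mass over the trivial one-state model on the training
        data."""
        trajs, _ = self._two_state_projections(n=4000, n_traj=4)
        res = gmrq_cross_validate(trajs, [1, 2, 5], lag_frames=1, n_folds=2,
                                  n_timescales=1, seed=1)
        train_mean = np.nanmean(res.train_scores, axis=1)
        assert train_mean[0] == pytest.approx(1.0, abs=1e-9)
        assert (train_mean[1:] >= train_mean[0] - 1e-9).all()

    def test_needs_two_trajectories(self):
        with pytest.raises(ValueError):
            gmrq_cross_validate([np.zeros((10, 1))], [2], lag_frames=1)


class TestBootstrap:
    def test_identical_trajectories_zero_sem(self):
        seq = sample_chain(np.array([[0.9, 0.1], [0.1, 0.9]]), 3000, seed=0)
        ens = bootstrap_models([seq.copy() for _ in range(4)], 1, n_boot=5,
                               seed=1, n_timescales=1)
        np.testing.assert_allclose(ens.sem["timescales"], 0.0, atol=1e-12)

    def test_bit_reproducible_for_fixed_seed(self):
        T = np.array([[0.93, 0.07], [0.04, 0.96]])
        seqs = [sample_chain(T, 2000, seed=s) for s in range(5)]
        a = bootstrap_models(seqs, 2, n_boot=5, seed=7)
        b = bootstrap_models(seqs, 2, n_boot=5, seed=7)
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra["timescales"],
                                          rb["timescales"])
        assert a.mean["pi_entropy"] == b.mean["pi_entropy"]

    def test_two_state_truth_within_three_sem(self):
        p = 0.02
        T = np.array([[1 - p, p], [p, 1 - p]])
        t_true = -1.0 / np.log(1 - 2 * p)
        seqs = [sample_chain(T, 20000, seed=s) for s in range(10)]
        ens = bootstrap_models(seqs, 1, n_boot=5, seed=3, n_timescales=1)
        err = abs(ens.mean["timescales"][0] - t_true)
        assert err <= 3 * max(ens.sem["timescales"][0], 0.02 * t_true)

    def test_rejects_single_trajectory(self):
        with pytest.raises(ValueError):
            bootstrap_models([np.zeros(10, dtype=int)], 1)
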