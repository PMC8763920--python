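"""Generator correctness: detailed balance, exact-equilibrium agreement,
staple monotonicity and nucleation-limited slow-down."""

import math

import numpy as np
import pytest

from helixmsm.helixcoil import (ENUMERATION_LIMIT, ExactMethodUnsupportedError,
                                HelixCoilParams, StateTrajectory,
                                _delta_log_weight, equilibrium_helicity_exact,
                                log_weight, relaxation_time_exact,
                                simulate_helix_coil,
                                stationary_distribution_exact)


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            HelixCoilParams(n_res=0, sigma=0.1, s=1.0)
        with pytest.raises(ValueError):
            HelixCoilParams(n_res=5, sigma=-0.1, s=1.0)
        with pytest.raises(ValueError):
            HelixCoilParams(n_res=5, sigma=0.1, s=1.0, staple_bonus=0.5)
        with pytest.raises(ValueError):
            HelixCoilParams(n_res=5, sigma=0.1, s=1.0, staple=(3, 3))
        with pytest.raises(ValueError):
            HelixCoilParams(n_res=5, sigma=0.1, s=1.0, staple=(0, 5))

    def test_nonpositive_frames_rejected(self, small_params):
        with pytest.raises(ValueError):
            simulate_helix_coil(small_params, 0)


class TestExactEquilibrium:
    def test_single_residue_two_state(self):
        """n=1 has partition function 1 + sigma*s."""
        p = HelixCoilParams(n_res=1, sigma=0.5, s=2.0)
        expected = 0.5 * 2.0 / (1 + 0.5 * 2.0)
        assert equilibrium_helicity_exact(p) == pytest.approx([expected])

    def test_enumeration_matches_direct_16_state(self):
        """n=4 probabilities recomputed from an independent 16-state sum."""
        p = HelixCoilParams(n_res=4, sigma=0.05, s=3.0)
        probs = np.zeros(4)
        z = 0.0
        for code in range(16):
            x = [(code >> r) & 1 for r in range(4)]
            runs = sum(1 for r in range(4)
                       if x[r] == 1 and (r == 0 or x[r - 1] == 0))
            w = (p.sigma ** runs) * (p.s ** sum(x))
            z += w
            probs += w * np.array(x)
        np.testing.assert_allclose(equilibrium_helicity_exact(p), probs / z,
                                   rtol=1e-12)

    def test_transfer_matrix_matches_enumeration(self):
        p = HelixCoilParams(n_res=12, sigma=0.02, s=1.4)
        from helixmsm.helixcoil import _transfer_matrix_helicity
        np.testing.assert_allclose(_transfer_matrix_helicity(p),
                                   equilibrium_helicity_exact(p), atol=1e-12)

    def test_staple_bonus_raises_every_residue(self):
        base = dict(n_res=9, sigma=0.05, s=1.2, staple=(2, 6))
        p1 = HelixCoilParams(**base, staple_bonus=1.0)
        p2 = HelixCoilParams(**base, staple_bonus=2.0)
        h1 = equilibrium_helicity_exact(p1)
        h2 = equilibrium_helicity_exact(p2)
        assert (h2 >= h1 - 1e-15).all()
        assert h2.mean() > h1.mean()

    def test_stapled_beyond_enumeration_limit_unsupported(self):
        p = HelixCoilParams(n_res=ENUMERATION_LIMIT + 2, sigma=0.05, s=1.2,
                            staple=(2, 6), staple_bonus=2.0)
        with pytest.raises(ExactMethodUnsupportedError):
            equilibrium_helicity_exact(p)


class TestDetailedBalance:
    def test_incremental_delta_matches_full_log_weight(self):
        """The O(1) flip bookkeeping must equal logw(y) - logw(x) for every
        single-site flip, which is exactly the detailed-balance identity for
        the Glauber kernel."""
        rng = np.random.default_rng(3)
        p = HelixCoilParams(n_res=10, sigma=0.03, s=1.5, staple=(2, 8),
                            staple_bonus=2.5)
        ls, lsig = math.log(p.s), math.log(p.sigma)
        lj = math.log(p.staple_bonus)
        for _ in range(200):
            x = rng.integers(0, 2, size=10).astype(np.int8)
            i = int(rng.integers(0, 10))
            y = x.copy()
            y[i] = 1 - y[i]
            d = _delta_log_weight(x.tolist(), i, p, lsig, ls, lj)
            assert d == pytest.approx(log_weight(y, p) - log_weight(x, p),
                                      abs=1e-12)


class TestSimulation:
    def test_reproducible_given_seed(self, small_params):
        a = simulate_helix_coil(small_params, 50, seed=42)
        b = simulate_helix_coil(small_params, 50, seed=42)
        np.testing.assert_array_equal(a.states, b.states)

    def test_vanishing_propagation_weight_gives_coil(self):
        p = HelixCoilParams(n_res=6, sigma=0.1, s=1e-6,
                            flip_attempts_per_frame=6, seed=2)
        st = simulate_helix_coil(p, 2000)
        assert st.states[100:].mean() < 0.01

    @pytest.mark.parametrize("n_res,sigma,s,staple,bonus", [
        (1, 0.5, 2.0, None, 1.0),
        (3, 0.1, 2.0, None, 1.0),
        (4, 0.05, 3.0, None, 1.0),
        (8, 0.05, 1.3, (1, 5), 2.0),
    ])
    def test_long_run_matches_exact_equilibrium(self, n_res, sigma, s,
                                                staple, bonus):
        """Per-residue occupation from independent chains agrees with the
        enumeration oracle within 3 Monte-Carlo SEM."""
        p = HelixCoilParams(n_res=n_res, sigma=sigma, s=s, staple=staple,
                            staple_bonus=bonus,
                            flip_attempts_per_frame=max(3, n_res))
        exact = equilibrium_helicity_exact(p)
        n_chains, n_frames, burn = 24, 1500, 200
        means = np.array([
            simulate_helix_coil(p, n_frames, seed=100 + c)
            .states[burn:].mean(axis=0)
            for c in range(n_chains)
        ])
        mc = means.mean(axis=0)
        sem = means.std(axis=0, ddof=1) / np.sqrt(n_chains)
        assert (np.abs(mc - exact) <= 3 * sem + 1e-9).all()

    def test_staple_monotonicity_paired_seeds(self):
        """Mean helicity is non-decreasing in the staple bonus J when the
        random stream is held fixed."""
        wins = 0
        for seed in range(8):
            hs = []
            for bonus in (1.0, 3.0):
                p = HelixCoilParams(n_res=12, sigma=0.02, s=1.1,
                                    staple=(4, 8), staple_bonus=bonus,
                                    flip_attempts_per_frame=12)
                st = simulate_helix_coil(p, 3000, seed=seed)
                hs.append(st.states[300:].mean())
            wins += hs[1] > hs[0]
        assert wins >= 7


class TestRelaxation:
    def test_exact_relaxation_small_chain_dense_oracle(self):
        """Sparse eigensolve agrees with a dense eigendecomposition of the
        full flip kernel."""
        p = HelixCoilParams(n_res=5, sigma=0.05, s=1.5,
                            flip_attempts_per_frame=5, frame_dt=0.5)
        from helixmsm.helixcoil import _attempt_kernel
        P, lw = _attempt_kernel(p)
        lams = np.sort(np.linalg.eigvals(P.toarray()).real)
        t_dense = -p.frame_dt / (p.flip_attempts_per_frame
                                 * np.log(lams[-2]))
        assert relaxation_time_exact(p) == pytest.approx(t_dense, rel=1e-8)

    def test_nucleation_limited_slowdown(self):
        """Smaller sigma (rarer nucleation) slows helix-coil relaxation."""
        times = [
            relaxation_time_exact(
                HelixCoilParams(n_res=10, sigma=sigma, s=1.2,
                                flip_attempts_per_frame=10)
            )
            for sigma in (0.3, 0.05, 0.01)
        ]
        assert times[0] < times[1] < times[2]

    def test_simulated_autocorrelation_tracks_exact_relaxation(self):
        """The empirical autocorrelation of total helicity decays on the
        oracle's relaxation timescale."""
        p = HelixCoilParams(n_res=8, sigma=0.05, s=1.3,
                            flip_attempts_per_frame=8, frame_dt=1.0)
        t_exact = relaxation_time_exact(p)
        sims = [simulate_helix_coil(p, 6000, seed=s).helicity_per_frame()
                for s in range(10)]
        lag = max(1, int(round(t_exact)))
        acs = []
        for h in sims:
            h = h[500:] - h[500:].mean()
            acs.append((h[:-lag] * h[lag:]).mean() / (h * h).mean())
        ac = np.mean(acs)
        assert ac == pytest.approx(np.exp(-lag / t_exact), abs=0.1)


def test_stationary_distribution_normalized(default_params):
    pi, bits = stationary_distribution_exact(default_params)
    assert pi.sum() == pytest.approx(1.0)
    assert bits.shape == (2 ** 15, 15)
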