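"""The 7-state LTCC Markov scheme, cooperativity factors, GHK current and
cluster simulation, checked against closed forms and master-equation
oracles."""

import math

import numpy as np
import pytest
import scipy.linalg

from coopgate import constants as K
from coopgate.ltcc import (LtccClusterState, LtccParams, TRANSITIONS,
                           advance_cluster, cluster_current, coupling_factors,
                           generator_matrix, ltcc_rates, opening_statistics,
                           simulate_cluster, single_channel_current)


@pytest.fixture
def params():
    return LtccParams()


def stationary(Q: np.ndarray) -> np.ndarray:
    """Null-space stationary distribution of a generator matrix."""
    w, vl = scipy.linalg.eig(Q.T)
    i = np.argmin(np.abs(w))
    pi = np.real(vl[:, i])
    return pi / pi.sum()


class TestCouplingFactors:
    def test_disabled_coupling_is_identity(self, params):
        g1, g2 = coupling_factors(4, 17.0, params.uncoupled())
        assert g1 == 1.0 and g2 == 1.0

    def test_double_midpoint_gives_quarter_weight(self):
        """With both logistic terms at their midpoint each contributes 1/2,
        so gamma = 1 + w/4."""
        p = LtccParams(w1=2.0, w2=4.0, po_x=1.0, cp_x=10.0)
        g1, g2 = coupling_factors(3, 10.0, p)  # N_L/3 = po_x, c_p = cp_x
        assert g1 == pytest.approx(1.0 + 2.0 / 4.0)
        assert g2 == pytest.approx(1.0 + 4.0 / 4.0)

    def test_saturation_limit(self, params):
        g1, g2 = coupling_factors(25, 1000.0, params)
        assert g1 == pytest.approx(1.0 + params.w1, rel=1e-6)
        assert g2 == pytest.approx(1.0 + params.w2, rel=1e-6)

    def test_monotone_in_open_count_and_cleft_ca(self, params):
        gs = [coupling_factors(n, 5.0, params)[0] for n in range(0, 10)]
        assert np.all(np.diff(gs) >= 0)
        gs = [coupling_factors(2, c, params)[0] for c in np.linspace(0, 30, 20)]
        assert np.all(np.diff(gs) >= 0)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            coupling_factors(-1, 1.0, params)
        with pytest.raises(ValueError):
            coupling_factors(1, -1.0, params)


class TestRates:
    def test_logistic_midpoint_at_zero_voltage(self, params):
        r = ltcc_rates(0.0, 1.0, 0, params.uncoupled())
        assert r.alpha / r.beta == pytest.approx(1.0)

    def test_ca_sensitivity_midpoint(self, params):
        """At c_p equal to the f(c_p) midpoint, s1 and k1 take half their
        maximal values."""
        r = ltcc_rates(0.0, params.cp_tilde, 0, params)
        assert r.s1 == pytest.approx(params.s1_bar / 2.0)
        assert r.k1 == pytest.approx(params.k1_bar / 2.0)

    def test_inactivation_recovery_split_at_minus_40(self, params):
        """Both voltage-partition functions equal 1/2 at V = -40 mV, where
        their exponents vanish."""
        import coopgate.ltcc as m
        assert m._logistic(-(-40.0 + 40.0) / 4.0) == 0.5
        assert m._logistic((-40.0 + 40.0) / 11.32) == 0.5

    def test_zero_cleft_ca_allowed(self, params):
        r = ltcc_rates(-20.0, 0.0, 0, params)
        assert r.s1 == 0.0 and r.k1 == 0.0 and r.k6 == 0.0
        for name in ("alpha", "beta", "r1", "r2", "k3", "k4", "k5"):
            assert np.isfinite(getattr(r, name))

    def test_detailed_balance_relations(self, params):
        """The detailed-balance constraints hold at base rates:
        s2 = s1 (k2/k1)/(r1/r2) and k4 = k3 (a/b)(k1/k2)(k5/k6).  With
        coupling enabled, gamma_2 speeds the opening rate only, so s2 is
        still computed from the uncoupled r1."""
        u = params.uncoupled()
        r = ltcc_rates(-10.0, 2.0, 2, u)
        assert r.s2 == pytest.approx(r.s1 * (r.k2 / r.k1) / (r.r1 / r.r2))
        ab = r.alpha / r.beta
        assert r.k4 == pytest.approx(ab * r.k3 * (r.k1 / r.k2) * (r.k5 / r.k6),
                                     rel=1e-9)
        assert r.k4p == pytest.approx(ab * r.k3p * (r.k1p / r.k2p)
                                      * (r.k5p / r.k6p), rel=1e-9)
        rc = ltcc_rates(-10.0, 2.0, 2, params)
        assert rc.s2 == pytest.approx(r.s2)  # unchanged by coupling

    @pytest.mark.parametrize("V", [-120.0, -80.0, -40.0, 0.0, 40.0, 80.0])
    @pytest.mark.parametrize("cp", [0.0, 0.5, 5.0, 100.0])
    def test_rates_nonnegative_and_finite(self, V, cp, params):
        r = ltcc_rates(V, cp, 3, params)
        for _, _, name in TRANSITIONS:
            v = getattr(r, name)
            assert np.isfinite(v) and v >= 0.0


class TestSingleChannelCurrent:
    def test_zero_voltage_limit(self, params):
        """The removable singularity at V = 0 equals the analytic limit
        2 P_Ca F (0.001 gamma_i c_p - gamma_o Ca_o)."""
        expect = 2.0 * params.p_ca * K.FARADAY * (
            0.001 * params.gamma_i * 0.5 - params.gamma_o * params.ca_o)
        assert single_channel_current(0.0, 0.5, params) == pytest.approx(expect)
        assert single_channel_current(1e-9, 0.5, params) == pytest.approx(
            expect, rel=1e-5)

    def test_reversal_potential_root(self, params):
        cp = 100.0
        v_rev = params.rt_f / 2.0 * math.log(
            params.gamma_o * params.ca_o / (0.001 * params.gamma_i * cp))
        assert single_channel_current(v_rev, cp, params) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_evaluation(self, params):
        """Direct re-evaluation of the GHK-type expression at +20 mV."""
        V = 20.0
        for cp in (0.1, 10.0, 300.0):
            z = V / params.rt_f
            expect = (4.0 * params.p_ca * z * K.FARADAY
                      * (0.001 * params.gamma_i * cp * np.exp(2 * z)
                         - params.gamma_o * params.ca_o) / (np.exp(2 * z) - 1.0))
            assert single_channel_current(V, cp, params) == pytest.approx(expect)
        vals = [single_channel_current(V, cp, params) for cp in (0.1, 10.0, 300.0)]
        assert vals[0] < vals[1] < vals[2]  # increasing in c_p

    def test_inward_at_plateau(self, params):
        assert single_channel_current(0.0, 0.5, params) < 0.0
        assert single_channel_current(20.0, 0.5, params) < 0.0


class TestCluster:
    def test_cluster_current_is_linear_in_open_count(self, params):
        st = LtccClusterState(np.array([K.LTCC_O] * 5 + [K.LTCC_C2] * 5))
        i1 = single_channel_current(10.0, 1.0, params)
        assert cluster_current(st, 10.0, 1.0, params) == pytest.approx(5 * i1)
        rest = LtccClusterState.resting(10)
        assert cluster_current(rest, 10.0, 1.0, params) == 0.0

    def test_dt_bound_enforced(self, params):
        st = LtccClusterState.resting(3)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="substep"):
            advance_cluster(st, 0.0, 1.0, 1.0, rng, params)

    def test_occupancy_conserved_and_reproducible(self, params):
        t, n1 = simulate_cluster(8, 0.0, 2.0, 50.0, 0.01, seed=5, params=params)
        t, n2 = simulate_cluster(8, 0.0, 2.0, 50.0, 0.01, seed=5, params=params)
        assert np.array_equal(n1, n2)
        t, n3, hist = simulate_cluster(4, 0.0, 2.0, 10.0, 0.01, seed=1,
                                       params=params, record_states=True)
        assert hist.shape[1] == 4
        assert np.all((hist >= 0) & (hist <= 6))

    def test_single_channel_matches_master_equation(self, params):
        """Long-run occupancy of a 1-channel cluster matches the stationary
        distribution of the 7x7 generator (null-space solve), within
        3 Monte-Carlo standard errors on each state."""
        p = params.uncoupled()
        V, cp = 0.0, 1.0
        pi = stationary(generator_matrix(V, cp, 0, p))
        from coopgate._kernels import params_array, run_cluster_clamped
        P = params_array(p)
        dt = 0.01
        n_steps = 4_000_000
        # track full state occupancy via many independent short chains is
        # costlier; here the single long trace of the open state suffices
        # for the open probability, and a 25-channel independent cluster
        # (uncoupled channels are independent) gives all-state occupancy.
        trace = run_cluster_clamped(1, V, cp, n_steps, dt, 11, P)
        burn = n_steps // 10
        po_hat = trace[burn:].mean()
        # effective sample size from the slowest relaxation time of Q
        Q = generator_matrix(V, cp, 0, p)
        ev = np.linalg.eigvals(Q)
        tau = 1.0 / min(-e.real for e in ev if abs(e) > 1e-12)
        n_eff = (n_steps - burn) * dt / (2.0 * tau)
        se = math.sqrt(pi[K.LTCC_O] * (1 - pi[K.LTCC_O]) / n_eff)
        assert abs(po_hat - pi[K.LTCC_O]) < 3.0 * se

    def test_two_channel_cluster_matches_joint_chain_oracle(self, params):
        """With coupling, a 2-channel cluster's stationary open-count
        distribution matches the brute-force stationary distribution of the
        exact 49-state joint generator with n_open-dependent rates."""
        p = LtccParams(w1=3.0, w2=3.0, po_x=0.1, cp_x=2.0)
        V, cp = 0.0, 4.0

        # exact joint generator over ordered pairs (s1, s2)
        def idx(a, b):
            return 7 * a + b

        Q = np.zeros((49, 49))
        rate_cache = {}
        for a in range(7):
            for b in range(7):
                n_open = (a == K.LTCC_O) + (b == K.LTCC_O)
                if n_open not in rate_cache:
                    rate_cache[n_open] = ltcc_rates(V, cp, n_open, p)
                r = rate_cache[n_open]
                for i, j, name in TRANSITIONS:
                    k = getattr(r, name)
                    if a == i:
                        Q[idx(a, b), idx(j, b)] += k
                    if b == i:
                        Q[idx(a, b), idx(a, j)] += k
        Q[np.diag_indices(49)] -= Q.sum(axis=1)
        pi = stationary(Q)
        # marginal distribution of the open count
        pn = np.zeros(3)
        for a in range(7):
            for b in range(7):
                pn[(a == K.LTCC_O) + (b == K.LTCC_O)] += pi[idx(a, b)]

        from coopgate._kernels import params_array, run_cluster_clamped
        P = params_array(p)
        dt = 0.01
        n_steps = 4_000_000
        trace = run_cluster_clamped(2, V, cp, n_steps, dt, 23, P)
        burn = n_steps // 10
        hat = np.array([(trace[burn:] == k).mean() for k in range(3)])
        ev = np.linalg.eigvals(Q)
        tau = 1.0 / min(-e.real for e in ev if abs(e) > 1e-10)
        n_eff = (n_steps - burn) * dt / (2.0 * tau)
        for k in range(3):
            se = math.sqrt(max(pn[k] * (1 - pn[k]), 1e-12) / n_eff)
            assert abs(hat[k] - pn[k]) < 4.0 * se + 1e-4

    def test_open_probability_nondecreasing_in_w1(self):
        """Mean cluster open probability at fixed (V, c_p) grows with the
        coupling strength (shared seeds)."""
        from coopgate._kernels import params_array, run_cluster_clamped
        means = []
        for w in (0.0, 2.0, 6.0):
            p = LtccParams(w1=w, w2=w, po_x=0.1, cp_x=0.5)
            P = params_array(p)
            tr = run_cluster_clamped(10, 0.0, 4.0, 400_000, 0.01, 99, P)
            means.append(tr[40_000:].mean())
        assert means[0] < means[1] < means[2]

    def test_coupling_promotes_simultaneous_openings(self):
        """Events with >= 2 simultaneous openings are relatively more
        frequent with coupling than without at matched conditions."""
        from coopgate._kernels import params_array, run_cluster_clamped
        freqs = {}
        for name, p in (("off", LtccParams().uncoupled()),
                        ("on", LtccParams(w1=4.0, w2=4.0, po_x=0.1, cp_x=2.0))):
            P = params_array(p)
            tr = run_cluster_clamped(10, 0.0, 4.0, 600_000, 0.01, 7, P)
            mx, dw = opening_statistics(np.asarray(tr), 0.01)
            freqs[name] = np.mean(mx >= 2)
        assert freqs["on"] > freqs["off"]


class TestOpeningStatistics:
    def test_hand_countable_trace(self):
        mx, dwell = opening_statistics(np.array([0, 0, 1, 2, 1, 0]), 1.0)
        assert mx.tolist() == [2]
        assert dwell.tolist() == [3.0]

    def test_all_zero_and_empty(self):
        mx, dwell = opening_statistics(np.zeros(10), 0.5)
        assert mx.size == 0 and dwell.size == 0
        mx, dwell = opening_statistics(np.array([]), 0.5)
        assert mx.size == 0

    def test_recovers_known_event_structure(self):
        from coopgate.io import make_fixture
        trace, truth = make_fixture("n_open_events", seed=4)
        mx, dwell = opening_statistics(trace, truth["dt"])
        assert mx.size == len(truth["events"])
        for k, ev in enumerate(truth["events"]):
            assert mx[k] == ev["max"]
            assert dwell[k] == pytest.approx(ev["dwell"])
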