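"""Closed-form G2 propagation, inverse moments and the fast waiting time."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from cmega import (
    PoissonCascade,
    approx_inverse_moment,
    effective_rates_griffith,
    effective_rates_switch,
    fast_tau,
    g_griffith,
    h_g_switch,
    lambda_griffith,
    lambda_switch,
    poisson_inverse_moment,
    survival_Q,
    survival_q_griffith,
    survival_q_switch,
)
from cmega.networks import GRIFFITH_PARAMS, SWITCH_PARAMS
from cmega.poisson import _int_exp_poly

SP = SWITCH_PARAMS
GP = GRIFFITH_PARAMS


class TestEffectiveRates:
    def test_free_promoter_no_mrna(self):
        qt, Kt = effective_rates_switch((1, 0, 0, 0), SP)
        assert qt == pytest.approx(SP["alpha1"] + SP["q"])
        assert Kt == pytest.approx(SP["r0"])

    def test_saturated_promoter(self):
        # from S2 no binding channel remains and transcription runs at r
        qt, Kt = effective_rates_switch((0, 0, 1, 3), SP)
        assert qt == pytest.approx(SP["q"])
        assert Kt == pytest.approx(SP["beta2"] + SP["r"] + (SP["K"] + SP["k"]) * 3)

    def test_silent_g1_limit(self):
        p = dict(SP, alpha1=0.0, alpha2=0.0, beta1=0.0, beta2=0.0,
                 r0=0.0, r=0.0, k=0.0, K=0.0)
        qt, Kt = effective_rates_switch((1, 0, 0, 5), p)
        assert qt == p["q"] and Kt == 0.0

    def test_griffith_includes_decay_by_default(self):
        g1 = (0, 1, 0, 0, 0, 2)
        qt, _ = effective_rates_griffith(g1, GP)
        assert qt == pytest.approx(GP["alpha2"] + GP["q"])
        qt_lit, _ = effective_rates_griffith(g1, GP, literal_printed=True)
        assert qt_lit == pytest.approx(GP["alpha2"])

    def test_one_hot_enforced(self):
        with pytest.raises(ValueError):
            effective_rates_switch((1, 1, 0, 0), SP)


class TestSwitchClosedForms:
    def test_lambda_initial_and_fixed_point(self):
        assert lambda_switch(0.0, 7.0, SP["K"], 3, SP["q"]) == 7.0
        fp = SP["K"] * 3 / SP["q"]
        assert lambda_switch(50.0, fp, SP["K"], 3, SP["q"]) == pytest.approx(fp)

    def test_lambda_degenerate_no_decay(self):
        assert lambda_switch(10.0, 2.0, 1.0, 3, 0.0) == pytest.approx(32.0)

    def test_lambda_matches_ode(self):
        m, lam0 = 2, 0.0
        sol = solve_ivp(
            lambda t, y: [SP["K"] * m - SP["q"] * y[0]], (0, 100), [lam0],
            t_eval=[100.0], rtol=1e-11, atol=1e-12,
        )
        assert lambda_switch(100.0, lam0, SP["K"], m, SP["q"]) == pytest.approx(
            sol.y[0, -1], abs=1e-8
        )

    @pytest.mark.parametrize("g1_state", [(1, 0, 0, 2), (0, 1, 0, 4), (0, 0, 1, 1)])
    def test_h_g_match_their_odes(self, g1_state):
        lam0 = 7.0
        qt, Kt = effective_rates_switch(g1_state, SP)
        m = g1_state[3]

        def rhs(_t, y):
            return [SP["K"] * m - qt * y[0], Kt - SP["q"] * y[0]]

        sol = solve_ivp(rhs, (0, 50), [lam0, lam0], t_eval=[50.0],
                        rtol=1e-11, atol=1e-12)
        h, g = h_g_switch(50.0, lam0, g1_state, SP)
        assert h == pytest.approx(sol.y[0, -1], abs=1e-8)
        assert g == pytest.approx(sol.y[1, -1], abs=1e-8)

    def test_h_g_initial_condition(self):
        h, g = h_g_switch(0.0, 11.0, (1, 0, 0, 2), SP)
        assert h == 11.0 and g == 11.0

    def test_silent_g1_gives_unit_survival(self):
        p = dict(SP, alpha1=0.0, alpha2=0.0, beta1=0.0, beta2=0.0,
                 r0=0.0, r=0.0, k=0.0)
        for tau in [0.0, 1.0, 10.0, 100.0]:
            assert survival_q_switch(tau, 5.0, (1, 0, 0, 2), p) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_survival_monotone_from_one(self):
        taus = np.linspace(0.0, 20.0, 50)
        q = [survival_q_switch(t, 10.0, (1, 0, 0, 1), SP) for t in taus]
        assert q[0] == 1.0
        assert np.all(np.diff(q) < 0)
        assert np.all((np.array(q) > 0) & (np.array(q) <= 1))


class TestGriffithClosedForms:
    def test_initial_condition(self):
        lam0 = np.array([3.0, 1.0, 4.0])
        assert np.allclose(lambda_griffith(0.0, lam0, GP["K"], 5, GP["a"], GP["q"]), lam0)

    def test_long_time_steady_state(self):
        m = 4
        lam = lambda_griffith(
            2000.0, np.zeros(5), GP["K"], m, GP["a"], GP["q"]
        )
        assert np.allclose(lam[:-1], GP["K"] * m / GP["a"], rtol=1e-9)
        assert lam[-1] == pytest.approx(GP["K"] * m / GP["q"], rel=1e-9)

    @pytest.mark.parametrize("a,q", [(GP["a"], GP["q"]), (0.1, 0.1), (0.05, 0.1)])
    def test_matches_ode_including_rate_collision(self, a, q):
        d, m = 3, 5
        lam0 = np.array([3.0, 1.0, 4.0])

        def rhs(_t, y):
            return [GP["K"] * m - a * y[0], a * (y[0] - y[1]), a * y[1] - q * y[2]]

        for t in [0.5, 5.0, 50.0]:
            sol = solve_ivp(rhs, (0, t), lam0, t_eval=[t], rtol=1e-12, atol=1e-13)
            got = lambda_griffith(t, lam0, GP["K"], m, a, q)
            assert np.allclose(got, sol.y[:, -1], atol=1e-7)

    def test_g_normalizes_survival_to_one(self):
        lam0 = np.array([2.0, 3.0, 1.0, 4.0])
        g1 = (1, 0, 0, 0, 0, 2)
        assert g_griffith(0.0, lam0, g1, GP) == pytest.approx(lam0.sum())
        assert survival_q_griffith(0.0, lam0, g1, GP) == 1.0

    def test_g_constant_integrand_case(self):
        # initial means pinned at the h-cascade fixed point make h_d constant
        m = 2
        g1 = (0, 1, 0, 0, 0, m)
        qt, Kt = effective_rates_griffith(g1, GP)
        lam0 = np.array([GP["K"] * m / GP["a"]] * 3 + [GP["K"] * m / qt])
        t = 7.0
        expected = lam0.sum() + (Kt - GP["q"] * GP["K"] * m / qt) * t
        assert g_griffith(t, lam0, g1, GP, method="closed") == pytest.approx(expected)

    def test_g_derivative_matches_Ktilde_minus_q_hd(self):
        from cmega.poisson import h_griffith

        lam0 = np.array([1.0, 6.0, 2.0, 3.0])
        g1 = (0, 0, 1, 0, 0, 3)
        _, Kt = effective_rates_griffith(g1, GP)
        t, dt = 4.0, 1e-5
        dg = (
            g_griffith(t + dt, lam0, g1, GP, method="closed")
            - g_griffith(t - dt, lam0, g1, GP, method="closed")
        ) / (2 * dt)
        hd = h_griffith(t, lam0, g1, GP)[-1]
        assert dg == pytest.approx(Kt - GP["q"] * hd, abs=1e-6)

    def test_g_quadrature_equals_closed_form(self):
        lam0 = np.array([3.0, 1.0, 4.0, 2.0, 6.0])
        g1 = (1, 0, 0, 0, 0, 4)
        for t in [0.3, 2.0, 9.0]:
            assert g_griffith(t, lam0, g1, GP, method="quad") == pytest.approx(
                g_griffith(t, lam0, g1, GP, method="closed"), abs=1e-9
            )

    def test_survival_monotone(self):
        lam0 = np.array([5.0, 5.0, 40.0])
        g1 = (1, 0, 0, 0, 0, 2)
        taus = np.linspace(0, 10, 40)
        q = [survival_q_griffith(t, lam0, g1, GP) for t in taus]
        assert q[0] == 1.0 and np.all(np.diff(q) < 0)


class TestIntExpPoly:
    @pytest.mark.parametrize("c", [-2.0, -0.3, 0.0, 0.04, 1.0, 7.0, 40.0])
    @pytest.mark.parametrize("t", [0.1, 1.0, 4.0])
    def test_against_quadrature(self, c, t):
        jmax = 8
        got = _int_exp_poly(c, t, jmax)
        for j in range(jmax + 1):
            ref, _ = quad(lambda s: math.exp(-c * s) * s**j, 0, t,
                          epsabs=1e-14, epsrel=1e-13)
            assert got[j] == pytest.approx(ref, rel=1e-10, abs=1e-13)


class TestInverseMoments:
    def test_zero_mean_is_reciprocal(self):
        assert poisson_inverse_moment(2.5, 0.0) == 0.4
        assert approx_inverse_moment(2.5, 0.0) == pytest.approx(0.4)

    def test_unit_shift_identity(self):
        for lam in [0.3, 3.0, 40.0, 4000.0]:
            assert poisson_inverse_moment(1.0, lam) == pytest.approx(
                (1 - math.exp(-lam)) / lam, rel=1e-13
            )

    def test_brute_force_small_case(self):
        a, lam = 2.5, 3.0
        term, total = math.exp(-lam), 0.0
        for n in range(200):
            if n:
                term *= lam / n
            total += term / (n + a)
        assert poisson_inverse_moment(a, lam) == pytest.approx(total, rel=1e-13)

    def test_nonpositive_a_rejected(self):
        with pytest.raises(ValueError):
            poisson_inverse_moment(0.0, 1.0)
        with pytest.raises(ValueError):
            approx_inverse_moment(-1.0, 1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        a=st.floats(0.05, 60.0),
        lam=st.floats(0.0, 80.0),
    )
    def test_series_matches_brute_force(self, a, lam):
        term, total = math.exp(-lam), 0.0
        for n in range(400):
            if n:
                term *= lam / n
            total += term / (n + a)
        assert poisson_inverse_moment(a, lam) == pytest.approx(total, rel=1e-12)

    def test_expansion_accurate_in_large_regime(self):
        exact = poisson_inverse_moment(100.0, 50.0)
        assert abs(approx_inverse_moment(100.0, 50.0) / exact - 1) < 1e-4

    def test_expansion_degrades_for_small_arguments(self):
        # the documented caveat: lam, a below one
        exact = poisson_inverse_moment(0.5, 0.5)
        rel = abs(approx_inverse_moment(0.5, 0.5) / exact - 1)
        assert rel > 1e-2


class TestFastTau:
    def test_pure_exponential_reduction(self):
        tau, ok = fast_tau(0.5, 2.0, 0.0)
        assert ok and tau == pytest.approx(math.log(2) / 2)

    def test_xi_near_one_always_fast(self):
        tau, ok = fast_tau(1 - 1e-12, 1.0, 5.0)
        assert ok and tau == pytest.approx(0.0, abs=1e-11)

    def test_nonpositive_b1_forces_fallback(self):
        tau, ok = fast_tau(0.5, 0.0, 0.1)
        assert not ok and math.isnan(tau)

    def test_against_quadratic_root(self):
        b1, b2, xi = 1.0, 0.1, 0.5
        tau0, ok = fast_tau(xi, b1, b2, eps=0.05)
        assert ok
        L = math.log(1 / xi)
        exact = (b1 - math.sqrt(b1 * b1 - 2 * b2 * L)) / b2
        assert abs(tau0 - exact) / exact < 0.05

    def test_b1_is_g1_propensity_sum_at_mean(self, switch):
        lam = 37.5
        casc = PoissonCascade("switch", [lam], 0, 2, switch.params)
        b1, _ = casc.b_coeffs()
        state = [1, 0, 0, 2, lam]
        assert b1 == pytest.approx(switch.g1_propensities(state).sum())

    def test_b1_griffith_matches_propensity_sum(self, griffith):
        lam = np.full(10, 20.0)
        casc = PoissonCascade("griffith", lam, 1, 3, griffith.params)
        b1, _ = casc.b_coeffs()
        state = np.zeros(griffith.n_species)
        state[1] = 1
        state[griffith.index("m")] = 3
        state[griffith.index("n10")] = 20.0
        assert b1 == pytest.approx(griffith.g1_propensities(state).sum())


class TestSurvivalQDispatch:
    def test_generic_entry_point(self, switch):
        casc = PoissonCascade("switch", [10.0], 0, 1, switch.params)
        assert survival_Q(0.0, casc) == 1.0
        assert survival_Q(2.0, casc) == pytest.approx(
            survival_q_switch(2.0, 10.0, (1, 0, 0, 1), switch.params)
        )
        with pytest.raises(ValueError):
            survival_Q(-1.0, casc)
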