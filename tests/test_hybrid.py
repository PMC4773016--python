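"""The hybrid loop: waiting times, reaction probabilities, resets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson as poi

from cmega import (
    HybridState,
    apply_reaction_and_reset,
    build_switch,
    lambda_switch,
    reaction_probs_griffith,
    reaction_probs_switch,
    run_hybrid,
    run_hybrid_ensemble,
    sample_tau,
    select_next_reaction,
)
from cmega.fixtures import generate_fixture
from cmega.hybrid import _g1_counts_switch, lhat_down, run_hybrid_exact_switch, shift_up
from cmega.networks import GRIFFITH_PARAMS, SWITCH_PARAMS
from cmega.oracle import (
    TruncatedDistribution,
    default_shape,
    integrate_Q,
    marginal_reaction_probs,
    poisson_lattice,
)


class TestSampleTau:
    def test_xi_one_gives_zero(self):
        st_ = HybridState("switch", 0, 1, [10.0])
        assert sample_tau(st_, 1.0, SWITCH_PARAMS)[0] == 0.0

    def test_pure_exponential_regime(self):
        # from S2 the G1 propensity sum is constant: tau = ln(1/xi)/b1
        st_ = HybridState("switch", 2, 4, [50.0])
        p = SWITCH_PARAMS
        b1 = p["beta2"] + p["r"] + p["k"] * 4
        tau, fast = sample_tau(st_, 0.37, p)
        assert fast
        assert tau == pytest.approx(math.log(1 / 0.37) / b1, rel=1e-12)

    def test_root_hits_oracle_survival(self, switch):
        st_ = HybridState("switch", 0, 1, [10.0])
        tau, _ = sample_tau(st_, 0.3, switch.params, eps=1e-12)  # force exact path
        _, surv = integrate_Q(
            switch, [1, 0, 0, 1], poisson_lattice([10.0], (120,)), tau
        )
        assert abs(surv - 0.3) < 1e-9

    def test_silent_g1_returns_sentinel(self):
        p = dict(SWITCH_PARAMS, alpha1=0.0, alpha2=0.0, beta1=0.0, beta2=0.0,
                 r0=0.0, r=0.0, k=0.0)
        st_ = HybridState("switch", 0, 1, [10.0])
        tau, _ = sample_tau(st_, 0.5, p)
        assert math.isinf(tau)


class TestReactionProbsSwitch:
    def test_saturated_promoter_closed_form(self):
        p = SWITCH_PARAMS
        m = 3
        st_ = HybridState("switch", 2, m, [123.0])
        tot = p["beta2"] + p["r"] + p["k"] * m
        probs = reaction_probs_switch(st_, p)
        assert probs[3] == pytest.approx(p["beta2"] / tot)
        assert probs[4] == pytest.approx(p["r"] / tot)
        assert probs[5] == pytest.approx(p["k"] * m / tot)
        assert probs[[0, 1, 2]].sum() == 0.0

    def test_no_mrna_no_decay_probability(self):
        probs = reaction_probs_switch(HybridState("switch", 0, 0, [5.0]), SWITCH_PARAMS)
        assert probs[5] == 0.0

    @pytest.mark.parametrize("mode", ["exact", "series"])
    def test_probabilities_sum_to_one(self, mode):
        for st_ in generate_fixture("states", 21, "switch", 25):
            probs = reaction_probs_switch(st_, SWITCH_PARAMS, mode=mode)
            assert np.all(probs >= 0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_lattice_marginalization(self, switch):
        # brute-force marginalization over the truncated Poisson lattice
        for st_ in generate_fixture("states", 22, "switch", 20):
            lam = float(st_.lam[0])
            shape = (int(lam + 12 * math.sqrt(max(lam, 1)) + 60),)
            dist = TruncatedDistribution(poisson_lattice([lam], shape), ["n"])
            ref = marginal_reaction_probs(switch, _g1_counts_switch(st_.s, st_.m), dist)
            got = reaction_probs_switch(st_, switch.params, mode="exact")
            assert np.allclose(got, ref, atol=1e-8)


class TestReactionProbsGriffith:
    def test_fully_repressed_promoter(self):
        p = GRIFFITH_PARAMS
        m = 2
        st_ = HybridState("griffith", 4, m, np.full(10, 40.0))
        probs = reaction_probs_griffith(st_, p)
        tot = p["beta4"] + p["k"] * m
        assert probs[7] == pytest.approx(p["beta4"] / tot)
        assert probs[9] == pytest.approx(p["k"] * m / tot)
        assert probs.sum() == pytest.approx(1.0)

    def test_no_mrna_unbinding_certain(self):
        probs = reaction_probs_griffith(
            HybridState("griffith", 4, 0, np.full(10, 40.0)), GRIFFITH_PARAMS
        )
        assert probs[7] == 1.0

    def test_matches_marginal_over_mature_species(self, griffith):
        # only n_d enters the G1 propensities: sum over its Poisson marginal
        for st_ in generate_fixture("states", 23, "griffith", 15):
            lam_d = float(st_.lam[-1])
            nmax = int(lam_d + 12 * math.sqrt(max(lam_d, 1)) + 60)
            pmf = poi.pmf(np.arange(nmax), lam_d)
            base = np.zeros(griffith.n_species)
            base[griffith.g1_species] = [*np.eye(5)[st_.s], st_.m]
            ref = np.zeros(10)
            idx_nd = griffith.index("n10")
            for nd, w in enumerate(pmf):
                full = base.copy()
                full[idx_nd] = nd
                a = griffith.g1_propensities(full)
                tot = a.sum()
                if tot > 0:
                    ref += w * a / tot
            got = reaction_probs_griffith(st_, griffith.params, mode="exact")
            assert np.allclose(got, ref, atol=1e-8)


class TestSelectNextReaction:
    def test_certain_channel(self):
        assert select_next_reaction([1.0, 0.0, 0.0], 0.9) == 0

    def test_cumulative_boundary(self):
        assert select_next_reaction([0.25, 0.75], 0.5) == 1
        assert select_next_reaction([0.25, 0.75], 0.2) == 0

    def test_frequencies(self, rng):
        p = np.array([0.1, 0.6, 0.3])
        n = 50_000
        draws = np.array([select_next_reaction(p, x) for x in rng.random(n)])
        counts = np.bincount(draws, minlength=3)
        assert np.all(np.abs(counts - n * p) <= 3 * np.sqrt(n * p * (1 - p)))


class TestDistributionUpdates:
    def test_delta_shift_down(self):
        w = np.zeros(10)
        w[5] = 1.0
        out = lhat_down(w, 1)
        assert out[4] == 1.0 and out.sum() == 1.0

    def test_delta_shift_up(self):
        w = np.zeros(6)
        w[2] = 1.0
        out = shift_up(w, 1)
        assert out[3] == 1.0

    def test_pileup_formula_truncated_poisson(self):
        w = poi.pmf(np.arange(30), 3.0)
        out = lhat_down(w, 1)
        assert out[0] == pytest.approx(w[0] + w[1])
        assert np.allclose(out[1:], w[2:])

    def test_all_mass_at_zero_stays(self):
        w = np.zeros(5)
        w[0] = 1.0
        out = lhat_down(w, 1)
        assert out[0] == 1.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        lam=st.floats(0.1, 8.0),
        w=st.integers(1, 3),
    )
    def test_pileup_conserves_mass(self, lam, w):
        weights = poi.pmf(np.arange(60), lam)
        out = lhat_down(weights, w)
        assert out.sum() == pytest.approx(weights.sum(), abs=1e-12)
        assert np.all(out >= 0)


class TestApplyReactionAndReset:
    def test_transcription_carries_advanced_lambda(self, switch):
        st_ = HybridState("switch", 0, 2, [7.0])
        tau = 3.0
        new = apply_reaction_and_reset(st_, 4, tau, switch)
        p = switch.params
        assert new.m == 3 and new.s == 0
        assert new.t == pytest.approx(tau)
        assert new.lam[0] == pytest.approx(
            lambda_switch(tau, 7.0, p["K"], 2, p["q"])
        )

    def test_binding_updates_promoter_only_in_poisson_mode(self, switch):
        st_ = HybridState("switch", 0, 2, [7.0])
        new = apply_reaction_and_reset(st_, 0, 0.0, switch)
        assert new.s == 1 and new.m == 2
        assert new.lam[0] == pytest.approx(7.0)

    def test_exact_mode_applies_shift(self, switch):
        st_ = HybridState("switch", 1, 2, [0.0])
        w = np.zeros(12)
        w[5] = 1.0
        dist = TruncatedDistribution(w, ["n"])
        # unbind1 releases one protein: distribution shifts up
        new, nd = apply_reaction_and_reset(st_, 1, 0.0, switch, mode="exact", dist=dist)
        assert new.s == 0
        assert nd.weights[6] == 1.0

    def test_invalid_reaction_index(self, switch):
        with pytest.raises(ValueError):
            apply_reaction_and_reset(HybridState("switch", 0, 0, [0.0]), 6, 0.0, switch)


class TestRunHybrid:
    def test_seed_reproducibility(self, switch):
        a = run_hybrid(switch, t_final=80.0, seed=5)
        b = run_hybrid(switch, t_final=80.0, seed=5)
        assert np.array_equal(a.m, b.m) and np.array_equal(a.s, b.s)
        assert np.allclose(a.lam, b.lam)

    @pytest.mark.parametrize("model_fixture,t_final", [("switch", 100.0), ("griffith", 40.0)])
    def test_python_and_kernel_agree_on_shared_stream(
        self, model_fixture, t_final, switch, griffith, rng
    ):
        net = switch if model_fixture == "switch" else griffith
        u = rng.random(4000)
        grid = np.linspace(0.0, t_final, 21)
        py = run_hybrid(net, t_final=t_final, record_grid=grid, engine="python", u_stream=u)
        nb = run_hybrid(net, t_final=t_final, record_grid=grid, engine="numba", u_stream=u)
        assert np.array_equal(py.s, nb.s)
        assert np.array_equal(py.m, nb.m)
        assert np.allclose(py.lam, nb.lam, atol=1e-8)
        assert py.counters == nb.counters

    def test_silent_g1_lambda_relaxes_alone(self):
        tiny = 1e-14
        net = build_switch(alpha1=tiny, alpha2=tiny, beta1=tiny, beta2=tiny,
                           r0=tiny, r=tiny, k=tiny)
        grid = np.linspace(0.0, 200.0, 5)
        init = HybridState("switch", 0, 2, [50.0])
        traj = run_hybrid(net, init=init, t_final=200.0, record_grid=grid, seed=1)
        assert traj.counters["events"] == 0
        p = net.params
        expected = [lambda_switch(t, 50.0, p["K"], 2, p["q"]) for t in grid]
        assert np.allclose(traj.lam[:, 0], expected, rtol=1e-10)

    def test_counters_account_for_all_draws(self, switch):
        traj = run_hybrid(switch, t_final=120.0, seed=8)
        drawn = traj.counters["fast_path"] + traj.counters["exact_path"]
        assert drawn - traj.counters["events"] in (0, 1)

    def test_ensemble_columns_and_one_hot(self, griffith):
        grid = np.linspace(0.0, 30.0, 7)
        ens = run_hybrid_ensemble(griffith, t_final=30.0, n_runs=4, grid=grid, seed=2)
        prom = ens.states[:, :, :5]
        assert np.allclose(prom.sum(axis=2), 1.0)
        assert ens.columns[5] == "m" and ens.columns[-1] == "lam_n10"
        assert ens.counters["events"] > 0


class TestExactModeSwitch:
    def test_short_run_respects_invariants(self, switch):
        dist0 = TruncatedDistribution(poisson_lattice([5.0], (60,)), ["n"])
        events = run_hybrid_exact_switch(switch, dist0, 60.0, seed=3, max_events=40)
        assert (events["time"].diff().dropna() > 0).all()
        assert set(events["s"]).issubset({0, 1, 2})
        assert (events["m"] >= 0).all()
        assert (events["mean_n"] >= 0).all()
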