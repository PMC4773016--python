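"""Direct-method SSA: waiting times, reaction selection, trajectories."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cmega import (
    Trajectory,
    build_switch,
    default_initial_state,
    draw_waiting_time,
    run_ssa_ensemble,
    select_reaction,
    simulate_full,
)
from cmega.networks import Reaction, ReactionNetwork, Species
from cmega.ssa import spawn_child_seeds


def toy_decay_network(q=0.25):
    """Single death channel q*n."""
    return ReactionNetwork(
        "decay",
        [Species("n", "G1")],
        [Reaction(0, "death", ((q, (0,)),), (-1,), "G1")],
        {"q": q},
    )


def toy_birth_death(b=5.0, d=0.5):
    return ReactionNetwork(
        "bd",
        [Species("n", "G1")],
        [
            Reaction(0, "birth", ((b, ()),), (+1,), "G1"),
            Reaction(1, "death", ((d, (0,)),), (-1,), "G1"),
        ],
        {"b": b, "d": d},
    )


class TestDrawWaitingTime:
    def test_r1_one_gives_zero(self):
        assert draw_waiting_time(3.0, 1.0) == 0.0

    def test_analytic_inversion(self):
        assert draw_waiting_time(2.0, math.exp(-2.0)) == pytest.approx(1.0)

    def test_absorbing_state_signalled(self):
        assert draw_waiting_time(0.0, 0.5) == math.inf

    @pytest.mark.parametrize("r1", [0.0, -0.1, 1.5])
    def test_invalid_uniform_rejected(self, r1):
        with pytest.raises(ValueError):
            draw_waiting_time(1.0, r1)

    def test_distribution_is_exponential(self, rng):
        a0 = 1.7
        taus = np.array([draw_waiting_time(a0, r) for r in rng.random(100_000)])
        stat = sps.kstest(taus, sps.expon(scale=1 / a0).cdf)
        assert stat.pvalue > 0.01


class TestSelectReaction:
    def test_single_channel(self):
        assert select_reaction([1.0, 0.0, 0.0], 0.99) == 0

    def test_cumulative_boundary(self):
        # cumulative sums (1, 4); 1 > 0.2*4 selects the first channel
        assert select_reaction([1.0, 3.0], 0.2) == 0
        assert select_reaction([1.0, 3.0], 0.25) == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_reaction([0.0, 0.0], 0.5)

    def test_sampling_frequencies_multinomial(self, rng):
        props = np.array([0.5, 2.0, 1.0, 0.01])
        p = props / props.sum()
        n = 100_000
        draws = np.array([select_reaction(props, r) for r in rng.random(n)])
        counts = np.bincount(draws, minlength=4)
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * sigma + 1)


class TestTrajectory:
    def test_zero_order_hold_resampling(self):
        traj = Trajectory(
            [0.0, 1.0, 3.0], np.array([[0], [5], [2]]), ["n"]
        )
        grid = [0.0, 0.5, 1.0, 2.9, 3.0, 4.0]
        assert traj.resample(grid).ravel().tolist() == [0, 0, 5, 5, 2, 2]

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            Trajectory([0.0, 2.0, 1.0], np.zeros((3, 1)), ["n"])


class TestSimulateFull:
    def test_reproducibility(self, switch):
        init = default_initial_state(switch)
        a = simulate_full(switch, init, 40.0, seed=9)
        b = simulate_full(switch, init, 40.0, seed=9)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)

    def test_absorbing_state_holds_to_t_final(self):
        net = toy_decay_network()
        traj = simulate_full(net, [0], 10.0, seed=0)
        assert traj.times.tolist() == [0.0, 10.0]
        assert np.all(traj.states == 0)

    def test_pure_decay_ensemble_mean(self):
        net = toy_decay_network(q=0.25)
        n0, n_runs = 30, 2000
        grid = np.linspace(0.0, 10.0, 6)
        ens = run_ssa_ensemble(net, [n0], 10.0, n_runs, grid, seed=42)
        vals = ens.column("n")
        expected = n0 * np.exp(-net.params["q"] * grid)
        se = vals.std(axis=0, ddof=1) / np.sqrt(n_runs)
        assert np.all(np.abs(vals.mean(axis=0) - expected) <= 3 * se + 1e-9)

    def test_birth_death_stationary_poisson(self):
        net = toy_birth_death(b=5.0, d=0.5)  # stationary Poisson(10)
        grid = np.arange(50.0, 2000.0, 2.0)
        traj = simulate_full(net, [0], 2000.0, seed=7)
        samples = traj.resample(grid).ravel()
        assert abs(samples.mean() - 10.0) < 0.5
        assert abs(samples.var() - 10.0) < 1.5

    def test_invalid_inputs(self, switch):
        with pytest.raises(ValueError):
            simulate_full(switch, default_initial_state(switch), -1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_full(switch, [2, 0, 0, 0, 0], 1.0, seed=0)


class TestKernelEquivalence:
    """The compiled kernel and the Python loop consume an identical uniform
    stream and must produce the identical trajectory."""

    @pytest.mark.parametrize("factory,t_final", [
        (build_switch, 30.0),
        (lambda: toy_birth_death(), 20.0),
    ])
    def test_same_uniforms_same_path(self, factory, t_final, rng):
        from cmega import _kernels

        net = factory()
        init = (
            default_initial_state(net)
            if net.name == "switch"
            else np.zeros(1, dtype=np.int64)
        )
        u = rng.random(6000)
        grid = np.linspace(0.0, t_final, 13)
        py = simulate_full(net, init, t_final, u_stream=u).resample(grid)
        out = np.empty((len(grid), net.n_species), dtype=np.int64)
        _kernels.ssa_run(
            *net.to_arrays(), np.asarray(init, np.int64), t_final, grid,
            np.int64(0), u, out,
        )
        assert np.array_equal(py, out)


class TestEnsembleSeeding:
    def test_child_seeds_deterministic_and_distinct(self):
        a = spawn_child_seeds(5, 10)
        b = spawn_child_seeds(5, 10)
        assert np.array_equal(a, b)
        assert len(np.unique(a)) == 10

    def test_ensemble_reproducible(self, switch):
        grid = np.linspace(0, 20, 5)
        init = default_initial_state(switch)
        e1 = run_ssa_ensemble(switch, init, 20.0, 5, grid, seed=11)
        e2 = run_ssa_ensemble(switch, init, 20.0, 5, grid, seed=11)
        assert np.array_equal(e1.states, e2.states)
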