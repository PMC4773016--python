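"""Direct-method stochastic simulation (Gillespie) of the full network.

This is the ground-truth reference against which the hybrid simulator is
validated.  ``simulate_full`` is a readable pure-Python implementation used
for unit tests and small runs; ensembles go through the compiled kernels in
:mod:`cmega._kernels` (same mathematics, same random-number consumption
order, cross-checked by feeding both implementations an identical uniform
stream).

Reaction indices are 0-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .networks import ReactionNetwork


def draw_waiting_time(a0: float, r1: float) -> float:
    """Exponential waiting time tau = ln(1/r1)/a0.

    ``a0`` is the total propensity and ``r1`` a uniform variate in (0, 1].
    ``a0 == 0`` signals an absorbing state and returns ``inf`` (the caller
    jumps to the final time).
    """
    if not 0.0 < r1 <= 1.0:
        raise ValueError(f"r1 must lie in (0, 1], got {r1}")
    if a0 < 0.0:
        raise ValueError("total propensity must be non-negative")
    if a0 == 0.0:
        return math.inf
    return math.log(1.0 / r1) / a0


def select_reaction(propensities: Sequence[float], r2: float) -> int:
    """Smallest index j with cumulative propensity above ``r2 * a0``.

    Returns a 0-based reaction index.
    """
    props = np.asarray(propensities, dtype=float)
    if np.any(props < 0):
        raise ValueError("propensities must be non-negative")
    a0 = props.sum()
    if a0 <= 0.0:
        raise ValueError("all propensities are zero (absorbing state)")
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    threshold = r2 * a0
    acc = 0.0
    for j, a in enumerate(props):
        acc += a
        if acc > threshold:
            return j
    return len(props) - 1  # numerical guard; unreachable for exact sums


@dataclass
class Trajectory:
    """Event times and post-event states of one realization.

    ``times[0]`` is the initial time with the initial state; event times are
    strictly increasing.  ``resample`` evaluates the trajectory on a uniform
    grid by zero-order hold (the value at a grid point is the state after
    the last event at or before it).
    """

    times: np.ndarray
    states: np.ndarray
    species: list
    model: str = ""
    seed: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be non-decreasing")

    def resample(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=self.species)
        frame.insert(0, "time", self.times)
        return frame

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _uniform_pairs(rng, u_stream) -> Iterator[tuple]:
    if u_stream is not None:
        stream = iter(np.asarray(u_stream, dtype=float))
        while True:
            try:
                r1 = next(stream)
                r2 = next(stream)
            except StopIteration:
                return
            yield r1, r2
    else:
        while True:
            yield rng.random(), rng.random()


def simulate_full(
    network: ReactionNetwork,
    init_state: Sequence[int],
    t_final: float,
    seed=None,
    rng: np.random.Generator | None = None,
    u_stream: Sequence[float] | None = None,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Exact direct-method SSA trajectory of the full network.

    The trajectory is a pure function of (network, init, t_final, seed).
    ``u_stream`` substitutes an explicit sequence of uniforms (consumed as
    r1, r2 per event) for the generator — used to cross-check the compiled
    kernel.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    network.validate_state(init_state)
    if rng is None:
        rng = np.random.default_rng(seed)
    state = np.asarray(init_state, dtype=np.int64).copy()
    stoich = network.stoich_matrix
    t = 0.0
    times = [0.0]
    states = [state.copy()]
    pairs = _uniform_pairs(rng, u_stream)
    for _ in range(max_events):
        props = network.propensities(state)
        a0 = float(props.sum())
        if a0 == 0.0:
            break
        try:
            r1, r2 = next(pairs)
        except StopIteration:  # explicit stream exhausted
            break
        tau = draw_waiting_time(a0, max(r1, np.finfo(float).tiny))
        if t + tau > t_final:
            break
        mu = select_reaction(props, r2)
        state += stoich[mu]
        t += tau
        times.append(t)
        states.append(state.copy())
    else:  # pragma: no cover
        raise RuntimeError("max_events exceeded")
    # close the trajectory at t_final with the final state held
    times.append(t_final)
    states.append(state.copy())
    return Trajectory(
        np.array(times), np.array(states), network.species_names, network.name, seed
    )


def spawn_child_seeds(seed, n: int) -> np.ndarray:
    """Independent 32-bit child seeds for realization i = 0..n-1.

    Derived by numpy seed-sequence spawning so that ensembles are
    reproducible and independent of evaluation order.
    """
    return np.array(
        [ss.generate_state(1)[0] for ss in np.random.SeedSequence(seed).spawn(n)],
        dtype=np.uint32,
    )


def run_ssa_ensemble(
    network: ReactionNetwork,
    init_state: Sequence[int],
    t_final: float,
    n_runs: int,
    grid: np.ndarray,
    seed=None,
):
    """Ensemble of exact-SSA realizations recorded on ``grid`` (zero-order
    hold).  Returns an :class:`cmega.stats.EnsembleResult` with an array of
    shape (n_runs, len(grid), n_species)."""
    from . import _kernels
    from .stats import EnsembleResult

    network.validate_state(init_state)
    grid = np.asarray(grid, dtype=float)
    arrays = network.to_arrays()
    seeds = spawn_child_seeds(seed, n_runs)
    out = np.empty((n_runs, len(grid), network.n_species), dtype=np.int64)
    empty_u = np.empty(0)
    init = np.asarray(init_state, dtype=np.int64)
    for i in range(n_runs):
        _kernels.ssa_run(
            *arrays, init, float(t_final), grid, np.int64(seeds[i]), empty_u, out[i]
        )
    return EnsembleResult(
        grid=grid,
        states=out.astype(float),
        columns=list(network.species_names),
        model=network.name,
        method="ga",
        seed=seed,
    )


def first_g1_event_times(
    network: ReactionNetwork,
    g1_state: Sequence[int],
    lam0,
    n_runs: int,
    horizon: float,
    seed=None,
) -> np.ndarray:
    """Times of the first G1 reaction, starting from a fixed G1 state with
    G2 copy numbers drawn Poisson per realization.

    ``g1_state`` gives counts for the G1 species (in network order);
    ``lam0`` the Poisson mean(s) of the G2 species.  Runs that reach
    ``horizon`` without a G1 event are right-censored at ``horizon``
    (returned as ``inf``)."""
    from . import _kernels

    rng = np.random.default_rng(seed)
    arrays = network.to_arrays()
    lam0 = np.broadcast_to(np.asarray(lam0, dtype=float), (len(network.g2_species),))
    seeds = spawn_child_seeds(rng.integers(2**31), n_runs)
    times = np.empty(n_runs)
    init = np.zeros(network.n_species, dtype=np.int64)
    g1_idx = network.g1_species
    init[g1_idx] = np.asarray(g1_state, dtype=np.int64)
    for i in range(n_runs):
        init_i = init.copy()
        init_i[network.g2_species] = rng.poisson(lam0)
        t = _kernels.ssa_first_g1(
            *arrays, init_i, float(horizon), np.int64(seeds[i])
        )
        times[i] = t if t >= 0 else np.inf
    return times
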