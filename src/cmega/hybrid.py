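"""The hybrid CME/Gillespie loop.

Each cycle: (i) sample the waiting time ``tau`` of the next simulated (G1)
reaction from the survival function ``Q(tau)`` of the analytically
propagated sub-network — through the first-order fast path when the
quadratic-expansion ratio test accepts, otherwise by exact root finding;
(ii) pick the reaction from the probability vector obtained by averaging
each G1 propensity over the Poisson law of the hidden species; (iii) apply
the reaction to the G1 state and reset the G2 distribution, carrying the
advanced Poisson mean forward.

In the default ``poisson`` mode the +-1 change that binding/unbinding
events impose on the hidden pool is ignored (justified when the binding
rate constants are far below one), which keeps the G2 law exactly Poisson.
The ``exact`` validation mode instead propagates a truncated probability
vector with :mod:`cmega.oracle` and applies the shift / pile-up-at-zero
update operators literally.

Single trajectories run either through the pure-Python loop below or the
compiled kernels in :mod:`cmega._kernels`; ensembles always use the
kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from . import _kernels, oracle
from .networks import ReactionNetwork
from .poisson import PoissonCascade, fast_tau, inverse_moment
from .ssa import spawn_child_seeds

NO_EVENT = math.inf


@dataclass
class HybridState:
    """G1 counts plus the Poisson parameters of the hidden sub-network."""

    model: str
    s: int
    m: int
    lam: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if self.m < 0 or np.any(self.lam < 0):
            raise ValueError("invalid hybrid state")
        n_prom = 3 if self.model == "switch" else 5
        if not 0 <= self.s < n_prom:
            raise ValueError("promoter index out of range")

    def cascade(self, params: Dict[str, float]) -> PoissonCascade:
        return PoissonCascade(self.model, self.lam, self.s, self.m, params)


def sample_tau(
    state: HybridState,
    xi1: float,
    params: Dict[str, float],
    eps: float = 1e-3,
) -> tuple:
    """Waiting time to the next G1 reaction: solve ``Q(tau) = xi1``.

    Returns ``(tau, used_fast_path)``.  The fast path returns
    ``tau0 = ln(1/xi1)/b1`` when the ratio test accepts; otherwise the
    exact root is bracketed by doubling and polished to relative tolerance
    1e-12.  If Q stays above ``xi1`` (G1 effectively silent) the sentinel
    ``math.inf`` is returned.
    """
    if not 0.0 < xi1 < 1.0:
        if xi1 == 1.0:
            return 0.0, True
        raise ValueError("xi1 must lie in (0, 1)")
    casc = state.cascade(params)
    b1, b2 = casc.b_coeffs()
    if b1 <= 0.0:
        return NO_EVENT, False
    tau0, ok = fast_tau(xi1, b1, b2, eps)
    if ok:
        return tau0, True
    ln_xi = math.log(xi1)
    f = lambda tau: casc.log_survival(tau) - ln_xi  # noqa: E731
    hi = max(tau0, 1e-12)
    n_dbl = 0
    while f(hi) > 0.0:
        hi *= 2.0
        n_dbl += 1
        if n_dbl > 400:
            return NO_EVENT, False
    root = brentq(f, 0.0, hi, xtol=1e-300, rtol=1e-13, maxiter=200)
    return float(root), False


def reaction_probs_switch(
    state: HybridState, params: Dict[str, float], mode: str = "exact"
) -> np.ndarray:
    """Probability vector over the six switch G1 reactions.

    Order: (bind1, unbind1, bind2, unbind2, transcription, mRNA decay).
    Obtained by marginalizing each propensity over the Poisson protein law:
    with the G1 propensity sum ``c0 + c1*n``, constant channels contribute
    ``(rate/c1) <1/(n+A)>`` and the binding channel ``1 - A <1/(n+A)>``
    with ``A = c0/c1``, so the vector sums to one identically.
    """
    p = params
    lam = float(state.lam[0])
    m = state.m
    km = p["k"] * m
    out = np.zeros(6)
    if state.s == 0:
        A = (p["r0"] + km) / p["alpha1"]
        M = inverse_moment(A, lam, mode)
        out[0] = 1.0 - A * M
        out[4] = (p["r0"] / p["alpha1"]) * M
        out[5] = (km / p["alpha1"]) * M
    elif state.s == 1:
        A = (p["beta1"] + p["r0"] + km) / p["alpha2"]
        M = inverse_moment(A, lam, mode)
        out[2] = 1.0 - A * M
        out[1] = (p["beta1"] / p["alpha2"]) * M
        out[4] = (p["r0"] / p["alpha2"]) * M
        out[5] = (km / p["alpha2"]) * M
    else:
        tot = p["beta2"] + p["r"] + km
        out[3] = p["beta2"] / tot
        out[4] = p["r"] / tot
        out[5] = km / tot
    return out


def reaction_probs_griffith(
    state: HybridState, params: Dict[str, float], mode: str = "exact"
) -> np.ndarray:
    """Probability vector over the ten Griffith G1 reactions.

    Order: (bind1, unbind1, ..., bind4, unbind4, transcription, mRNA
    decay); only the mature conformation's marginal Poisson(lambda_d)
    enters.
    """
    p = params
    lam_d = float(state.lam[-1])
    m = state.m
    km = p["k"] * m
    out = np.zeros(10)
    s = state.s
    if s == 4:
        tot = p["beta4"] + km
        out[7] = p["beta4"] / tot
        out[9] = km / tot
        return out
    c1 = p[f"alpha{s + 1}"]
    c0 = (p["r"] if s == 0 else p[f"beta{s}"]) + km
    A = c0 / c1
    M = inverse_moment(A, lam_d, mode)
    out[2 * s] = 1.0 - A * M
    if s == 0:
        out[8] = (p["r"] / c1) * M
    else:
        out[2 * s - 1] = (p[f"beta{s}"] / c1) * M
    out[9] = (km / c1) * M
    return out


def reaction_probs(
    state: HybridState, params: Dict[str, float], mode: str = "exact"
) -> np.ndarray:
    if state.model == "switch":
        return reaction_probs_switch(state, params, mode)
    return reaction_probs_griffith(state, params, mode)


def select_next_reaction(p: Sequence[float], xi2: float) -> int:
    """Smallest index k with cumulative probability above xi2 (0-based)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if not 0.0 <= xi2 < 1.0:
        raise ValueError("xi2 must lie in [0, 1)")
    acc = 0.0
    for k, pk in enumerate(p):
        acc += pk
        if acc > xi2:
            return k
    return len(p) - 1


# -- distribution update operators (exact validation mode) ------------------


def shift_up(weights: np.ndarray, w: int = 1) -> np.ndarray:
    """Distribution update for a reaction that *adds* w hidden molecules:
    the new weight at n is the old weight at n - w."""
    out = np.zeros(len(weights) + w)
    out[w:] = weights
    return out


def lhat_down(weights: np.ndarray, w: int = 1) -> np.ndarray:
    """Pile-up-at-zero update for a reaction that *removes* w hidden
    molecules: mass from n <= w collapses onto 0, the rest shifts down
    (mass-conserving; no negative copy numbers)."""
    weights = np.asarray(weights, dtype=float)
    out = np.zeros(max(len(weights) - w, 1))
    out[0] = weights[: w + 1].sum()
    tail = weights[w + 1 :]
    out[1 : 1 + len(tail)] = tail
    return out


def apply_reaction_and_reset(
    state: HybridState,
    mu: int,
    tau: float,
    network: ReactionNetwork,
    params: Dict[str, float] | None = None,
    mode: str = "poisson",
    dist: Optional[oracle.TruncatedDistribution] = None,
):
    """Advance the clock by tau, fire G1 reaction ``mu`` and reset G2.

    In ``poisson`` mode the Poisson mean advanced to the event time is
    carried unchanged through the reaction (the +-1 from binding and
    unbinding is ignored).  In ``exact`` mode a truncated distribution must
    be supplied *already propagated to the event time*; reactions that add
    hidden molecules shift it up, reactions that remove them apply the
    pile-up-at-zero operator.  Returns the new state (and the new
    distribution in exact mode).
    """
    params = params if params is not None else network.params
    g1 = network.g1_reactions
    if not 0 <= mu < len(g1):
        raise ValueError("mu is not a G1 reaction index")
    rxn = g1[mu]
    casc = state.cascade(params)
    lam_t = casc.advance(tau).lam
    # update promoter / mRNA counts from the stoichiometry
    prom = network.promoter_species
    s_new = state.s
    for pos, i in enumerate(prom):
        if rxn.stoich[i] == 1:
            s_new = pos
    m_new = state.m + rxn.stoich[network.index("m")]
    new_state = replace(state, s=s_new, m=m_new, lam=lam_t, t=state.t + tau)
    if mode == "poisson":
        return new_state
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if dist is None:
        raise ValueError("exact mode needs the propagated distribution")
    w = dist.weights
    for pos, i in enumerate(network.g2_species):
        dv = rxn.stoich[i]
        if dv > 0:
            w = shift_up(w, dv)
        elif dv < 0:
            w = lhat_down(w, -dv)
    new_dist = oracle.TruncatedDistribution(w, dist.species, dist.normalized)
    return new_state, new_dist


# ---------------------------------------------------------------------------
# Trajectory containers and drivers
# ---------------------------------------------------------------------------


@dataclass
class HybridTrajectory:
    """G1 counts and G2 Poisson parameters on the recording grid."""

    grid: np.ndarray
    s: np.ndarray
    m: np.ndarray
    lam: np.ndarray  # (T, n_g2)
    model: str
    counters: Dict[str, int]
    seed: object = None
    events: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        n_prom = 3 if self.model == "switch" else 5
        data = {"time": self.grid}
        for j in range(n_prom):
            data[f"S{j}"] = (self.s == j).astype(int)
        data["m"] = self.m
        if self.lam.shape[1] == 1:
            data["lam_n"] = self.lam[:, 0]
        else:
            for j in range(self.lam.shape[1]):
                data[f"lam_n{j + 1}"] = self.lam[:, j]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _initial_hybrid_state(network: ReactionNetwork, init) -> HybridState:
    if isinstance(init, HybridState):
        return init
    if init is None:
        d = len(network.g2_species)
        return HybridState(network.name, 0, 0, np.zeros(d))
    raise TypeError("init must be a HybridState or None")


def _run_python(network, state, t_final, grid, rng, eps, mode, u_stream):
    """Readable reference loop; consumes uniforms in kernel order."""
    params = network.params
    ustream = iter(u_stream) if u_stream is not None else None

    def draw():
        if ustream is not None:
            return next(ustream)
        return rng.random()

    T = len(grid)
    out_s = np.empty(T, dtype=np.int64)
    out_m = np.empty(T, dtype=np.int64)
    out_lam = np.empty((T, len(state.lam)))
    gi = 0
    counters = {"events": 0, "fast_path": 0, "exact_path": 0}
    ev_rows = []
    while True:
        casc = state.cascade(params)
        b1, _ = casc.b_coeffs()
        if b1 <= 0.0:
            tau, used_fast = t_final - state.t + 1.0, True
        else:
            try:
                xi1 = draw()
            except StopIteration:
                break
            tau, used_fast = sample_tau(state, max(xi1, 1e-300), params, eps)
            if tau is NO_EVENT or math.isinf(tau):
                tau = t_final - state.t + 1.0
            else:
                counters["fast_path" if used_fast else "exact_path"] += 1
        t_next = state.t + tau
        while gi < T and grid[gi] < t_next:
            adv = casc.advance(grid[gi] - state.t)
            out_s[gi] = state.s
            out_m[gi] = state.m
            out_lam[gi] = adv.lam
            gi += 1
        if t_next >= t_final:
            break
        try:
            xi2 = draw()
        except StopIteration:
            break
        state = replace(state, lam=casc.advance(tau).lam, t=t_next)
        p = reaction_probs(state, params, mode)
        mu = select_next_reaction(p, xi2)
        state = apply_reaction_and_reset(state, mu, 0.0, network, params)
        counters["events"] += 1
        ev_rows.append((state.t, state.s, state.m, *state.lam))
    casc = state.cascade(params)
    while gi < T:
        adv = casc.advance(grid[gi] - state.t)
        out_s[gi] = state.s
        out_m[gi] = state.m
        out_lam[gi] = adv.lam
        gi += 1
    events = pd.DataFrame(
        ev_rows,
        columns=["time", "s", "m"] + [f"lam{i}" for i in range(len(state.lam))],
    )
    return out_s, out_m, out_lam, counters, events


def _run_kernel(network, state, t_final, grid, seed, eps, mode, u_stream,
                literal_qtilde=False):
    p = network.params
    T = len(grid)
    out_s = np.empty(T, dtype=np.int64)
    out_m = np.empty(T, dtype=np.int64)
    u = np.asarray(u_stream, dtype=float) if u_stream is not None else np.empty(0)
    exact_mom = mode == "exact"
    if network.name == "switch":
        out_lam = np.empty(T)
        n_ev, n_fast, n_exact, status = _kernels.hybrid_switch_run(
            p["alpha1"], p["alpha2"], p["beta1"], p["beta2"], p["r0"], p["r"],
            p["K"], p["k"], p["q"],
            state.s, state.m, float(state.lam[0]),
            float(t_final), grid, np.int64(seed if seed is not None else 0),
            eps, exact_mom, u, out_s, out_m, out_lam,
        )
        out_lam = out_lam[:, None]
    else:
        d = len(network.g2_species)
        out_lam = np.empty((T, d))
        alphas = np.array([p[f"alpha{i}"] for i in range(1, 5)])
        betas = np.array([p[f"beta{i}"] for i in range(1, 5)])
        n_ev, n_fast, n_exact, status = _kernels.hybrid_griffith_run(
            alphas, betas, p["r"], p["K"], p["k"], p["q"], p["a"],
            state.s, state.m, np.asarray(state.lam, dtype=float),
            float(t_final), grid, np.int64(seed if seed is not None else 0),
            eps, exact_mom, literal_qtilde, u, out_s, out_m, out_lam,
        )
    if status == _kernels.STATUS_ROOT_FAILURE:  # pragma: no cover
        raise RuntimeError("exact-path root finding failed in the kernel")
    counters = {"events": n_ev, "fast_path": n_fast, "exact_path": n_exact}
    return out_s, out_m, out_lam, counters, None


def run_hybrid(
    network: ReactionNetwork,
    init: HybridState | None = None,
    t_final: float = 500.0,
    seed=None,
    record_grid: np.ndarray | None = None,
    eps: float = 1e-3,
    inverse_moment_mode: str = "series",
    engine: str = "numba",
    u_stream=None,
) -> HybridTrajectory:
    """One hybrid realization recorded on ``record_grid``.

    ``engine="numba"`` runs the compiled kernel, ``engine="python"`` the
    reference loop; both consume the random stream identically, so a run
    with an explicit ``u_stream`` is directly comparable between engines.
    """
    if network.name not in ("switch", "griffith"):
        raise ValueError(f"no hybrid solver registered for {network.name!r}")
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    if record_grid is None:
        record_grid = np.linspace(0.0, t_final, 101)
    grid = np.asarray(record_grid, dtype=float)
    state = _initial_hybrid_state(network, init)
    mode = {"series": "series", "exact": "exact"}[inverse_moment_mode]
    if engine == "python":
        rng = np.random.default_rng(seed)
        out_s, out_m, out_lam, counters, events = _run_python(
            network, state, t_final, grid, rng, eps, mode, u_stream
        )
    elif engine == "numba":
        kseed = np.random.SeedSequence(seed).generate_state(1)[0] if u_stream is None else 0
        out_s, out_m, out_lam, counters, events = _run_kernel(
            network, state, t_final, grid, kseed, eps, mode, u_stream
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return HybridTrajectory(
        grid, out_s, out_m, out_lam, network.name, counters, seed, events
    )


def run_hybrid_ensemble(
    network: ReactionNetwork,
    init: HybridState | None = None,
    t_final: float = 500.0,
    n_runs: int = 100,
    grid: np.ndarray | None = None,
    seed=None,
    eps: float = 1e-3,
    inverse_moment_mode: str = "series",
    literal_qtilde: bool = False,
):
    """Ensemble of hybrid realizations on a common grid.

    Returns an :class:`cmega.stats.EnsembleResult` whose columns are the
    one-hot promoter indicators, the mRNA count and the Poisson mean(s) of
    the hidden species.  ``literal_qtilde`` selects the Griffith effective
    decay rate without the ``+q`` term (see
    :func:`cmega.poisson.effective_rates_griffith`)."""
    from .stats import EnsembleResult

    if grid is None:
        grid = np.linspace(0.0, t_final, 101)
    grid = np.asarray(grid, dtype=float)
    state = _initial_hybrid_state(network, init)
    seeds = spawn_child_seeds(seed, n_runs)
    n_prom = 3 if network.name == "switch" else 5
    d = len(network.g2_species)
    cols = [f"S{j}" for j in range(n_prom)] + ["m"]
    cols += ["lam_n"] if d == 1 else [f"lam_n{j + 1}" for j in range(d)]
    states = np.empty((n_runs, len(grid), len(cols)))
    counters = {"events": 0, "fast_path": 0, "exact_path": 0}
    for i in range(n_runs):
        out_s, out_m, out_lam, c, _ = _run_kernel(
            network, state, t_final, grid, int(seeds[i]), eps,
            inverse_moment_mode, None, literal_qtilde,
        )
        for j in range(n_prom):
            states[i, :, j] = out_s == j
        states[i, :, n_prom] = out_m
        states[i, :, n_prom + 1 :] = out_lam
        for key in counters:
            counters[key] += c[key]
    return EnsembleResult(
        grid=grid,
        states=states,
        columns=cols,
        model=network.name,
        method="cmega",
        seed=seed,
        counters=counters,
    )


# ---------------------------------------------------------------------------
# Exact validation mode (truncated-vector G2 distribution)
# ---------------------------------------------------------------------------


def run_hybrid_exact_switch(
    network: ReactionNetwork,
    init_dist: oracle.TruncatedDistribution,
    t_final: float,
    seed=None,
    record_grid: np.ndarray | None = None,
    max_events: int = 10_000,
) -> pd.DataFrame:
    """Hybrid loop for the switch with the G2 distribution propagated as an
    explicit truncated vector (no Poisson ansatz, no fast path).

    Validation tool: the waiting time is solved on the numerically
    integrated survival function and the shift / pile-up updates are
    applied literally.  Returns an event table (time, s, m, mean_n).
    """
    if network.name != "switch":
        raise ValueError("exact mode is implemented for the switch")
    rng = np.random.default_rng(seed)
    s, m, t = 0, 0, 0.0
    dist = init_dist
    rows = [(0.0, s, m, float(dist.mean()[0]))]
    for _ in range(max_events):
        g1_counts = _g1_counts_switch(s, m)
        nmax = len(dist.weights)
        Ap = oracle.g2_generator(network, g1_counts, (nmax,), include_g1_loss=False)
        Aq = oracle.g2_generator(network, g1_counts, (nmax,), include_g1_loss=True)
        Aq_d = Aq.toarray()
        xi1 = max(rng.random(), 1e-300)

        def log_surv(tau):
            w = expm(Aq_d * tau) @ dist.weights
            return math.log(max(w.sum(), 1e-300))

        ln_xi = math.log(xi1)
        hi = 1.0
        n_dbl = 0
        while log_surv(hi) > ln_xi:
            hi *= 2.0
            n_dbl += 1
            if n_dbl > 60:
                hi = None
                break
        if hi is None or t >= t_final:
            break
        tau = brentq(lambda x: log_surv(x) - ln_xi, 0.0, hi, rtol=1e-12)
        if t + tau >= t_final:
            break
        w_t = expm(Ap.toarray() * tau) @ dist.weights
        dist = oracle.TruncatedDistribution(
            np.clip(w_t, 0.0, None), dist.species, normalized=False
        )
        probs = oracle.marginal_reaction_probs(network, g1_counts, dist)
        mu = select_next_reaction(probs / probs.sum(), rng.random())
        state = HybridState("switch", s, m, [0.0], t)
        new_state, dist = apply_reaction_and_reset(
            state, mu, tau, network, mode="exact", dist=dist
        )
        # re-normalize and re-pad the carried distribution
        w = dist.weights / dist.total()
        if w[-1] > 1e-14:
            w = np.concatenate([w, np.zeros(20)])
        dist = oracle.TruncatedDistribution(w, dist.species)
        s, m, t = new_state.s, new_state.m, new_state.t
        rows.append((t, s, m, float(dist.mean()[0])))
    return pd.DataFrame(rows, columns=["time", "s", "m", "mean_n"])


def _g1_counts_switch(s: int, m: int):
    onehot = [0, 0, 0]
    onehot[s] = 1
    return np.array([*onehot, m], dtype=float)
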