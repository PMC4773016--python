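"""Partitioned mass-action reaction networks.

A :class:`ReactionNetwork` splits its reactions into two groups:

* **G1** — reactions that are simulated stochastically.  They may change any
  species (promoter indicators, mRNA, and — through binding/unbinding — the
  protein pool).
* **G2** — reactions that only touch the analytically-propagated species
  (the protein pool), whose master equation is solved in closed form.

Two built-in models are provided:

``build_switch``
    A single gene with positive autoregulation and promoter cooperativity 2.
    Promoter states ``S0`` (free), ``S1`` (one protein bound), ``S2`` (two
    bound); transcription is slow from ``S0``/``S1`` (basal rate ``r0``) and
    fast from ``S2`` (rate ``r``); the protein feeds back by binding its own
    promoter.

``build_griffith``
    A Griffith-type negative-feedback oscillator: transcription from the free
    promoter ``S0``, a protein that matures through ``d`` sequential
    conformations ``n1 → … → nd``, and a mature form ``nd`` that represses
    the promoter through four cooperative binding steps (``S1`` … ``S4``).

Promoter occupancy is encoded one-hot: each promoter state is its own
indicator species with value 0 or 1, so every propensity is a pure
mass-action product and stoichiometry vectors fully describe binding and
unbinding.  Rates are per-minute frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

G1 = "G1"
G2 = "G2"

#: Default rate constants (inverse minutes) for the genetic switch.
SWITCH_PARAMS: Dict[str, float] = {
    "alpha1": 1e-3,
    "alpha2": 1e-3,
    "beta1": 1.0,
    "beta2": 1.0,
    "r0": 0.1,
    "r": 10.0,
    "K": 1.0,
    "k": 0.05,
    "q": 0.01,
}

#: Default rate constants (inverse minutes) for the Griffith oscillator.
GRIFFITH_PARAMS: Dict[str, float] = {
    "alpha1": 0.01,
    "alpha2": 0.01,
    "alpha3": 0.01,
    "alpha4": 0.01,
    "beta1": 1.0,
    "beta2": 1.0,
    "beta3": 1.0,
    "beta4": 1.0,
    "r": 10.0,
    "K": 1.0,
    "k": 0.05,
    "q": 0.05,
    "a": 0.1,
}

GRIFFITH_DEFAULT_D = 10


@dataclass(frozen=True)
class Species:
    """A chemical species.

    ``kind`` is ``"count"`` for ordinary copy numbers and
    ``"promoter-indicator"`` for one-hot promoter-state indicators (which
    only ever take the values 0 and 1, exactly one being 1 per promoter).
    """

    name: str
    group: str
    kind: str = "count"

    def __post_init__(self) -> None:
        if self.group not in (G1, G2):
            raise ValueError(f"species group must be G1 or G2, got {self.group!r}")
        if self.kind not in ("count", "promoter-indicator"):
            raise ValueError(f"unknown species kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction with a mass-action propensity.

    The propensity is a *sum of mass-action terms*
    ``sum(rate * prod(state[i] for i in reactants))``.  Almost every reaction
    has a single term; the switch's transcription channel is the one compound
    reaction (``r0*S0 + r0*S1 + r*S2``) so that the reaction-probability
    vector of the hybrid matches the model's 6-way reaction grouping.
    """

    index: int
    name: str
    terms: Tuple[Tuple[float, Tuple[int, ...]], ...]
    stoich: Tuple[int, ...]
    group: str

    @property
    def rate_constant(self) -> float:
        return self.terms[0][0]

    def propensity(self, state: Sequence[float]) -> float:
        total = 0.0
        for rate, reactants in self.terms:
            term = rate
            for i in reactants:
                term *= state[i]
            total += term
        return total


@dataclass
class ReactionNetwork:
    """Species, reactions and the G1/G2 partition of a model."""

    name: str
    species: List[Species]
    reactions: List[Reaction]
    params: Dict[str, float]

    def __post_init__(self) -> None:
        n = len(self.species)
        g1_idx = {i for i, s in enumerate(self.species) if s.group == G1}
        for rxn in self.reactions:
            if len(rxn.stoich) != n:
                raise ValueError(
                    f"reaction {rxn.name!r}: stoichiometry has length "
                    f"{len(rxn.stoich)}, expected {n}"
                )
            for rate, _ in rxn.terms:
                if rate < 0:
                    raise ValueError(f"reaction {rxn.name!r}: negative rate")
            if rxn.group == G2:
                for i in g1_idx:
                    if rxn.stoich[i] != 0:
                        raise ValueError(
                            f"G2 reaction {rxn.name!r} changes G1 species "
                            f"{self.species[i].name!r}"
                        )

    # -- lookups ---------------------------------------------------------

    def index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(name)

    @property
    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def g1_species(self) -> List[int]:
        return [i for i, s in enumerate(self.species) if s.group == G1]

    @property
    def g2_species(self) -> List[int]:
        return [i for i, s in enumerate(self.species) if s.group == G2]

    @property
    def promoter_species(self) -> List[int]:
        return [
            i for i, s in enumerate(self.species) if s.kind == "promoter-indicator"
        ]

    @property
    def g1_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.group == G1]

    @property
    def g2_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.group == G2]

    @property
    def stoich_matrix(self) -> np.ndarray:
        """Integer matrix of shape (n_reactions, n_species)."""
        return np.array([r.stoich for r in self.reactions], dtype=np.int64)

    # -- evaluation ------------------------------------------------------

    def propensities(self, state: Sequence[float]) -> np.ndarray:
        return np.array([r.propensity(state) for r in self.reactions])

    def g1_propensities(self, state: Sequence[float]) -> np.ndarray:
        return np.array([r.propensity(state) for r in self.g1_reactions])

    def validate_state(self, state: Sequence[float]) -> None:
        state = np.asarray(state)
        if state.shape != (self.n_species,):
            raise ValueError("state has wrong dimension")
        if np.any(state < 0):
            raise ValueError("negative copy numbers")
        prom = self.promoter_species
        if prom:
            vals = state[prom]
            if not np.all(np.isin(vals, (0, 1))) or int(vals.sum()) != 1:
                raise ValueError("promoter indicators must be one-hot")

    def to_arrays(self):
        """Flat array form consumed by the numba kernels.

        Returns ``(term_rate, term_reactants, term_rxn, stoich, g1_mask)``
        where ``term_reactants`` is padded with -1.
        """
        terms = [(t, r.index) for r in self.reactions for t in r.terms]
        n_terms = len(terms)
        max_order = max((len(t[0][1]) for t in terms), default=0)
        term_rate = np.empty(n_terms)
        term_reactants = np.full((n_terms, max(max_order, 1)), -1, dtype=np.int64)
        term_rxn = np.empty(n_terms, dtype=np.int64)
        for j, ((rate, reactants), rxn_index) in enumerate(terms):
            term_rate[j] = rate
            for o, sp in enumerate(reactants):
                term_reactants[j, o] = sp
            term_rxn[j] = rxn_index
        g1_mask = np.array(
            [1 if r.group == G1 else 0 for r in self.reactions], dtype=np.int64
        )
        return term_rate, term_reactants, term_rxn, self.stoich_matrix, g1_mask


def _check_positive(params: Dict[str, float], keys: Sequence[str]) -> None:
    for key in keys:
        value = params.get(key)
        if value is None:
            raise ValueError(f"missing parameter {key!r}")
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {key!r} must be positive, got {value!r}")


def _merge(defaults: Dict[str, float], params, overrides) -> Dict[str, float]:
    merged = dict(defaults)
    for source in (params or {}), overrides:
        for key, value in source.items():
            if key not in defaults:
                raise ValueError(f"unknown parameter {key!r}")
            merged[key] = float(value)
    return merged


def build_switch(params: Dict[str, float] | None = None, **overrides) -> ReactionNetwork:
    """Build the positively autoregulated genetic switch.

    Species: ``S0, S1, S2`` (promoter one-hot, G1), ``m`` (mRNA, G1),
    ``n`` (protein, G2).  The six G1 reactions, in the grouping used by the
    hybrid's reaction-probability vector, are: binding x2, unbinding x2, a
    compound transcription channel ``r0*S0 + r0*S1 + r*S2`` and mRNA decay
    ``k*m``.  G2 holds translation ``K*m`` and protein decay ``q*n``.
    """
    p = _merge(SWITCH_PARAMS, params, overrides)
    _check_positive(p, SWITCH_PARAMS)
    species = [
        Species("S0", G1, "promoter-indicator"),
        Species("S1", G1, "promoter-indicator"),
        Species("S2", G1, "promoter-indicator"),
        Species("m", G1),
        Species("n", G2),
    ]
    iS0, iS1, iS2, im, in_ = range(5)

    def z():
        return [0, 0, 0, 0, 0]

    def stoich(**changes):
        s = z()
        for nm, dv in changes.items():
            s[{"S0": iS0, "S1": iS1, "S2": iS2, "m": im, "n": in_}[nm]] = dv
        return tuple(s)

    reactions = [
        Reaction(0, "bind1", ((p["alpha1"], (iS0, in_)),), stoich(S0=-1, S1=+1, n=-1), G1),
        Reaction(1, "unbind1", ((p["beta1"], (iS1,)),), stoich(S1=-1, S0=+1, n=+1), G1),
        Reaction(2, "bind2", ((p["alpha2"], (iS1, in_)),), stoich(S1=-1, S2=+1, n=-1), G1),
        Reaction(3, "unbind2", ((p["beta2"], (iS2,)),), stoich(S2=-1, S1=+1, n=+1), G1),
        Reaction(
            4,
            "transcription",
            ((p["r0"], (iS0,)), (p["r0"], (iS1,)), (p["r"], (iS2,))),
            stoich(m=+1),
            G1,
        ),
        Reaction(5, "mrna_decay", ((p["k"], (im,)),), stoich(m=-1), G1),
        Reaction(6, "translation", ((p["K"], (im,)),), stoich(n=+1), G2),
        Reaction(7, "protein_decay", ((p["q"], (in_,)),), stoich(n=-1), G2),
    ]
    return ReactionNetwork("switch", species, reactions, p)


def build_griffith(
    params: Dict[str, float] | None = None,
    d: int = GRIFFITH_DEFAULT_D,
    **overrides,
) -> ReactionNetwork:
    """Build the Griffith oscillator with ``d`` protein conformations.

    Species: ``S0..S4`` (promoter one-hot, G1), ``m`` (mRNA, G1) and the
    conformation cascade ``n1..nd`` (G2).  The mature form ``nd`` is the
    repressor that binds the promoter.  G1 reactions, in probability-vector
    order: (bind1, unbind1, bind2, unbind2, bind3, unbind3, bind4, unbind4,
    transcription ``r*S0``, mRNA decay ``k*m``).  G2 holds translation
    ``K*m -> n1``, the conversions ``a*ni`` and mature decay ``q*nd``.
    """
    if d < 2:
        raise ValueError(f"d must be >= 2, got {d}")
    p = _merge(GRIFFITH_PARAMS, params, overrides)
    _check_positive(p, GRIFFITH_PARAMS)
    species = [Species(f"S{i}", G1, "promoter-indicator") for i in range(5)]
    species.append(Species("m", G1))
    species.extend(Species(f"n{i}", G2) for i in range(1, d + 1))
    im = 5
    i_n = lambda j: 5 + j  # n_j lives at index 5+j (j = 1..d)  # noqa: E731
    n_sp = len(species)

    def stoich(changes):
        s = [0] * n_sp
        for idx, dv in changes.items():
            s[idx] = dv
        return tuple(s)

    reactions = []
    mu = 0
    for b in range(1, 5):
        sa, sb = b - 1, b  # S_{b-1} + nd -> S_b
        reactions.append(
            Reaction(
                mu,
                f"bind{b}",
                ((p[f"alpha{b}"], (sa, i_n(d))),),
                stoich({sa: -1, sb: +1, i_n(d): -1}),
                G1,
            )
        )
        mu += 1
        reactions.append(
            Reaction(
                mu,
                f"unbind{b}",
                ((p[f"beta{b}"], (sb,)),),
                stoich({sb: -1, sa: +1, i_n(d): +1}),
                G1,
            )
        )
        mu += 1
    reactions.append(
        Reaction(mu, "transcription", ((p["r"], (0,)),), stoich({im: +1}), G1)
    )
    mu += 1
    reactions.append(Reaction(mu, "mrna_decay", ((p["k"], (im,)),), stoich({im: -1}), G1))
    mu += 1
    reactions.append(
        Reaction(mu, "translation", ((p["K"], (im,)),), stoich({i_n(1): +1}), G2)
    )
    mu += 1
    for j in range(1, d):
        reactions.append(
            Reaction(
                mu,
                f"convert{j}",
                ((p["a"], (i_n(j),)),),
                stoich({i_n(j): -1, i_n(j + 1): +1}),
                G2,
            )
        )
        mu += 1
    reactions.append(
        Reaction(mu, "mature_decay", ((p["q"], (i_n(d),)),), stoich({i_n(d): -1}), G2)
    )
    net = ReactionNetwork("griffith", species, reactions, p)
    net.params["d"] = d
    return net


def default_initial_state(network: ReactionNetwork) -> np.ndarray:
    """Free promoter, no mRNA, no protein."""
    state = np.zeros(network.n_species, dtype=np.int64)
    state[network.index("S0")] = 1
    return state


# ---------------------------------------------------------------------------
# Mean-field (deterministic rate-equation) layer
# ---------------------------------------------------------------------------


@dataclass
class MeanFieldSystem:
    """Deterministic rate equations of a model.

    The state vector excludes the free-promoter fraction, which is recovered
    through the conservation closure ``S0 = 1 - sum(Si)``; the promoter
    fractions therefore sum to one identically along any solution.
    """

    network_name: str
    state_names: List[str]
    rhs: Callable[[float, np.ndarray], np.ndarray] = field(repr=False)

    def s0(self, y: np.ndarray) -> np.ndarray:
        n_ind = sum(1 for nm in self.state_names if nm.startswith("S"))
        y = np.asarray(y)
        return 1.0 - y[..., :n_ind].sum(axis=-1)


def mean_field_system(network: ReactionNetwork) -> MeanFieldSystem:
    p = network.params
    if network.name == "switch":
        a1, a2 = p["alpha1"], p["alpha2"]
        b1, b2 = p["beta1"], p["beta2"]
        r0, r, K, k, q = p["r0"], p["r"], p["K"], p["k"], p["q"]

        def rhs(_t, y):
            S1, S2, m, n = y
            S0 = 1.0 - S1 - S2
            return np.array(
                [
                    a1 * n * S0 + b2 * S2 - (a2 * n + b1) * S1,
                    a2 * S1 * n - b2 * S2,
                    r * S2 + r0 - k * m,
                    K * m - q * n,
                ]
            )

        return MeanFieldSystem("switch", ["S1", "S2", "m", "n"], rhs)

    if network.name == "griffith":
        d = int(p["d"])
        al = [p[f"alpha{i}"] for i in range(1, 5)]
        be = [p[f"beta{i}"] for i in range(1, 5)]
        r, K, k, q, a = p["r"], p["K"], p["k"], p["q"], p["a"]

        def rhs(_t, y):
            S = y[:4]  # S1..S4
            m = y[4]
            n = y[5:]
            S0 = 1.0 - S.sum()
            nd = n[-1]
            dS = np.empty(4)
            dS[0] = al[0] * nd * S0 + be[1] * S[1] - (al[1] * nd + be[0]) * S[0]
            dS[1] = al[1] * nd * S[0] + be[2] * S[2] - (al[2] * nd + be[1]) * S[1]
            dS[2] = al[2] * nd * S[1] + be[3] * S[3] - (al[3] * nd + be[2]) * S[2]
            dS[3] = al[3] * nd * S[2] - be[3] * S[3]
            dm = r * S0 - k * m
            dn = np.empty(d)
            dn[0] = K * m - a * n[0]
            for i in range(1, d - 1):
                dn[i] = a * (n[i - 1] - n[i])
            dn[d - 1] = a * n[d - 2] - q * nd
            return np.concatenate([dS, [dm], dn])

        names = [f"S{i}" for i in range(1, 5)] + ["m"] + [
            f"n{i}" for i in range(1, d + 1)
        ]
        return MeanFieldSystem("griffith", names, rhs)

    raise ValueError(f"no mean-field equations for model {network.name!r}")


def mean_field_rhs(network: ReactionNetwork, state: Sequence[float]) -> np.ndarray:
    """Right-hand side of the model's rate equations at ``state``."""
    system = mean_field_system(network)
    state = np.asarray(state, dtype=float)
    if state.shape != (len(system.state_names),):
        raise ValueError(
            f"state must have {len(system.state_names)} entries "
            f"({system.state_names})"
        )
    return system.rhs(0.0, state)


def integrate_mean_field(
    network: ReactionNetwork,
    t_grid: np.ndarray,
    y0: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the rate equations over ``t_grid`` (shape: len(grid) x dim)."""
    system = mean_field_system(network)
    if y0 is None:
        y0 = np.zeros(len(system.state_names))
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        system.rhs,
        (t_grid[0], t_grid[-1]),
        np.asarray(y0, dtype=float),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return sol.y.T
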