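"""Closed-form propagation of the non-simulated (G2) sub-network.

During an interval with no G1 reaction, the G2 sub-systems of both built-in
models are linear birth-death cascades.  A Poisson (or product-Poisson)
initial distribution therefore stays Poisson with a mean vector
``lambda(t)`` obeying linear ODEs, and the *unnormalized* distribution whose
lattice sum is the no-G1-reaction survival probability ``Q(tau)`` keeps the
same form ``exp(-g(t)) * prod h_i(t)^{n_i}/n_i!`` with

* ``h`` obeying the lambda equations with the mature-species decay rate
  ``q`` replaced by an effective rate ``q_tilde = q + (G1 binding
  coefficient)``, and
* ``g`` obeying ``dg/dt = K_tilde - q*h_last`` with ``K_tilde`` the
  copy-number-independent part of the total (G1+G2) propensity.

Everything here is a pure deterministic function; the hybrid loop composes
these primitives.

Conventions: promoter state is the index ``s`` of the indicator that is 1;
``m`` is the mRNA copy number; ``lam`` is the Poisson mean vector of the G2
species (length 1 for the switch, ``d`` for the Griffith cascade).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PoissonCascade",
    "effective_rates_switch",
    "effective_rates_griffith",
    "g1_linear_coeffs",
    "lambda_switch",
    "h_g_switch",
    "survival_q_switch",
    "lambda_griffith",
    "h_griffith",
    "g_griffith",
    "survival_q_griffith",
    "survival_Q",
    "poisson_inverse_moment",
    "approx_inverse_moment",
    "inverse_moment",
    "fast_tau",
]


# ---------------------------------------------------------------------------
# G1 propensity structure
#
# At a fixed G1 state every G1 propensity is either constant or proportional
# to the repressor/activator copy number (n for the switch, n_d for the
# Griffith cascade), so the G1 propensity sum is c0 + c1*n.  All effective
# rates derive from (c0, c1).
# ---------------------------------------------------------------------------


def _switch_onehot(g1_state: Sequence[float]) -> Tuple[int, int]:
    S0, S1, S2, m = g1_state
    svec = (S0, S1, S2)
    if tuple(sorted(svec)) != (0, 0, 1):
        raise ValueError("promoter state must be one-hot")
    if m < 0:
        raise ValueError("m must be non-negative")
    return int(np.argmax(svec)), int(m)


def _g1_coeffs_switch(s: int, m: int, p: Dict[str, float]) -> Tuple[float, float]:
    if s == 0:
        return p["r0"] + p["k"] * m, p["alpha1"]
    if s == 1:
        return p["beta1"] + p["r0"] + p["k"] * m, p["alpha2"]
    return p["beta2"] + p["r"] + p["k"] * m, 0.0


def _g1_coeffs_griffith(s: int, m: int, p: Dict[str, float]) -> Tuple[float, float]:
    c0 = p["k"] * m
    if s == 0:
        c0 += p["r"]
    else:
        c0 += p[f"beta{s}"]
    c1 = p[f"alpha{s + 1}"] if s < 4 else 0.0
    return c0, c1


def g1_linear_coeffs(model: str, s: int, m: int, params: Dict[str, float]):
    """(c0, c1) such that the G1 propensity sum equals ``c0 + c1 * n_last``."""
    if model == "switch":
        return _g1_coeffs_switch(s, m, params)
    if model == "griffith":
        return _g1_coeffs_griffith(s, m, params)
    raise ValueError(f"unknown model {model!r}")


def effective_rates_switch(
    g1_state: Sequence[float], params: Dict[str, float]
) -> Tuple[float, float]:
    """Effective rates (q_tilde, K_tilde) of the switch's survival equations.

    ``q_tilde = alpha1*S0 + alpha2*S1 + q`` and ``K_tilde`` is the
    copy-number-independent part of the total propensity,
    ``beta1*S1 + beta2*S2 + r0*(S0+S1) + r*S2 + (K+k)*m`` (the transcription
    term follows the model's compound propensity r0*S0 + r0*S1 + r*S2).
    """
    s, m = _switch_onehot(g1_state)
    c0, c1 = _g1_coeffs_switch(s, m, params)
    return c1 + params["q"], c0 + params["K"] * m


def effective_rates_griffith(
    g1_state: Sequence[float],
    params: Dict[str, float],
    literal_printed: bool = False,
) -> Tuple[float, float]:
    """Effective rates (q_tilde, K_tilde) of the Griffith survival equations.

    ``q_tilde = alpha1*S0 + ... + alpha4*S3 + q``: the binding channels add
    to — they do not replace — the mature-protein decay rate in the h
    cascade's last stage (substituting the product-Poisson ansatz into the
    survival master equation requires the ``+q``).  ``literal_printed=True``
    selects the variant without ``+q``.
    """
    svec = np.asarray(g1_state[:5])
    m = int(g1_state[5])
    s = int(np.argmax(svec))
    c0, c1 = _g1_coeffs_griffith(s, m, params)
    qt = c1 if literal_printed else c1 + params["q"]
    return qt, c0 + params["K"] * m


# ---------------------------------------------------------------------------
# Switch closed forms
# ---------------------------------------------------------------------------


def lambda_switch(t: float, lam0: float, K: float, m: float, q: float) -> float:
    """Poisson mean of the protein pool after time t at fixed mRNA count m."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if q == 0.0:
        return lam0 + K * m * t
    target = K * m / q
    return (lam0 - target) * math.exp(-q * t) + target


def h_g_switch(
    t: float,
    lam0: float,
    g1_state: Sequence[float],
    params: Dict[str, float],
) -> Tuple[float, float]:
    """The (h, g) pair of the switch's unnormalized survival distribution.

    ``h(0) = g(0) = lam0`` so that ``Q(0) = exp(lam0 - g(0)) = 1``.
    """
    s, m = _switch_onehot(g1_state)
    c0, c1 = _g1_coeffs_switch(s, m, params)
    K, q = params["K"], params["q"]
    qt = c1 + q
    Kt = c0 + K * m
    Km = K * m
    if qt == 0.0:  # only reachable when q == 0 and no binding channel
        h = lam0 + Km * t
        g = lam0 + Kt * t - q * (lam0 * t + 0.5 * Km * t * t)
        return h, g
    h = (lam0 - Km / qt) * math.exp(-qt * t) + Km / qt
    g = (
        (lam0 - Km / qt) * (q / qt) * (math.exp(-qt * t) - 1.0)
        + (Kt - Km * q / qt) * t
        + lam0
    )
    return h, g


def survival_q_switch(
    tau: float,
    lam0: float,
    g1_state: Sequence[float],
    params: Dict[str, float],
) -> float:
    """Probability that no G1 reaction fires within tau: exp(h - g)
    (the lattice sum of the unnormalized Poisson-form distribution)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    h, g = h_g_switch(tau, lam0, g1_state, params)
    return math.exp(h - g)


# ---------------------------------------------------------------------------
# Griffith closed forms
# ---------------------------------------------------------------------------


def _int_exp_poly(c: float, t: float, jmax: int) -> np.ndarray:
    """I_j = integral_0^t exp(-c*s) s^j ds for j = 0..jmax.

    Series evaluation near c*t ~ 0 (which also covers the a = q degenerate
    rate collision analytically), upward recursion otherwise.
    """
    out = np.zeros(jmax + 1)
    if t <= 0.0:
        return out
    x = c * t
    if x < jmax + 4:
        # I_j = t^{j+1} * sum_k (-x)^k / (k! (j+k+1)); fine for any x <~ 30,
        # and for strongly negative x the recursion below takes over.
        if x > -30.0:
            term = 1.0
            sums = np.zeros(jmax + 1)
            js = np.arange(jmax + 1)
            for kk in range(0, 300):
                if kk > 0:
                    term *= -x / kk
                sums += term / (js + kk + 1)
                if abs(term) < 1e-18 * (1.0 + np.abs(sums).max()) and kk > abs(x):
                    break
            tp = t
            for j in range(jmax + 1):
                out[j] = tp * sums[j]
                tp *= t
            return out
        # x << 0: integrand grows as exp(|c|s); recursion on the growing form
        b = -c
        out[0] = math.expm1(b * t) / b
        tp = t
        ebt = math.exp(b * t)
        for j in range(1, jmax + 1):
            out[j] = (tp * ebt - j * out[j - 1]) / b
            tp *= t
        return out
    out[0] = -math.expm1(-x) / c
    tp = t
    emx = math.exp(-x)
    for j in range(1, jmax + 1):
        out[j] = (j * out[j - 1] - tp * emx) / c
        tp *= t
    return out


def _cascade_body(t: float, lam0: np.ndarray, K: float, m: float, a: float):
    """lambda_i(t) for the conversion stages i < d (shared by lambda and h)."""
    d = len(lam0)
    Kma = K * m / a
    out = np.empty(d)
    e_at = math.exp(-a * t)
    # direct O(d^2) evaluation of the exponential-polynomial sums
    for i in range(d - 1):
        acc = 0.0
        atj = 1.0
        fact = 1.0
        for j in range(i + 1):
            if j > 0:
                atj *= a * t
                fact *= j
            acc += (Kma - lam0[i - j]) * atj / fact
        out[i] = Kma - e_at * acc
    return out


def _last_stage(
    t: float, lam0: np.ndarray, K: float, m: float, a: float, decay: float
) -> float:
    """Mean of the terminal species with decay rate ``decay`` (q or q_tilde)."""
    d = len(lam0)
    Km = K * m
    target = Km / decay
    val = target + (lam0[d - 1] - target) * math.exp(-decay * t)
    I = _int_exp_poly(a - decay, t, d - 2)
    Kma = Km / a
    s = 0.0
    apow = a
    fact = 1.0
    for j in range(d - 1):
        if j > 0:
            apow *= a
            fact *= j
        s += (apow / fact) * (Kma - lam0[d - 2 - j]) * I[j]
    return val - math.exp(-decay * t) * s


def lambda_griffith(
    t: float,
    lam0_vec: Sequence[float],
    K: float,
    m: float,
    a: float,
    q: float,
) -> np.ndarray:
    """Poisson mean vector of the conformation cascade after time t.

    Stages ``i < d`` relax toward ``K*m/a`` through the finite
    exponential-polynomial sum; the mature stage toward ``K*m/q`` through
    the incomplete-gamma (here: ``I_j``) sum.  The rate collision ``a == q``
    is handled by the series limit inside ``I_j``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    lam0 = np.asarray(lam0_vec, dtype=float)
    d = len(lam0)
    if d < 2:
        raise ValueError("the cascade needs at least two stages")
    out = np.empty(d)
    out[: d - 1] = _cascade_body(t, lam0, K, m, a)[: d - 1]
    out[d - 1] = _last_stage(t, lam0, K, m, a, q)
    # rounding in the alternating sums can leave ~1e-15 below zero
    if out.min() < -1e-9:
        raise FloatingPointError("cascade mean went significantly negative")
    np.clip(out, 0.0, None, out=out)
    return out


def h_griffith(
    t: float,
    lam0_vec: Sequence[float],
    g1_state: Sequence[float],
    params: Dict[str, float],
    literal_printed: bool = False,
) -> np.ndarray:
    """h vector of the Griffith survival distribution (h(0) = lambda(0)).

    Identical to :func:`lambda_griffith` except that the mature stage decays
    with q_tilde instead of q (the q -> q_tilde substitution only touches
    the last stage).
    """
    lam0 = np.asarray(lam0_vec, dtype=float)
    qt, _ = effective_rates_griffith(g1_state, params, literal_printed)
    m = float(g1_state[5])
    K, a = params["K"], params["a"]
    out = np.empty(len(lam0))
    out[:-1] = _cascade_body(t, lam0, K, m, a)[:-1]
    out[-1] = _last_stage(t, lam0, K, m, a, qt)
    return out


def _int_hd(
    T: float,
    lam0: np.ndarray,
    K: float,
    m: float,
    a: float,
    qt: float,
) -> float:
    """integral_0^T h_d(t) dt in closed form (I_j reduction)."""
    d = len(lam0)
    Km = K * m
    base = (Km / qt) * T + (lam0[d - 1] - Km / qt) * (-math.expm1(-qt * T)) / qt
    Ia = _int_exp_poly(a, T, d - 2)
    Iaq = _int_exp_poly(a - qt, T, d - 2)
    eqT = math.exp(-qt * T)
    Kma = Km / a
    s = 0.0
    apow = a
    fact = 1.0
    for j in range(d - 1):
        if j > 0:
            apow *= a
            fact *= j
        s += (apow / fact) * (Kma - lam0[d - 2 - j]) * (Ia[j] - eqT * Iaq[j]) / qt
    return base - s


def g_griffith(
    t: float,
    lam0_vec: Sequence[float],
    g1_state: Sequence[float],
    params: Dict[str, float],
    method: str = "quad",
    literal_printed: bool = False,
) -> float:
    """g(t) of the Griffith survival distribution.

    ``g(t) = sum(lam(0)) + K_tilde*t - q*int_0^t h_d``; the additive
    normalization ``g(0) = sum(lam(0))`` makes ``Q(0) = 1`` exactly.
    ``method="quad"`` integrates h_d by adaptive quadrature (abs tol 1e-10);
    ``method="closed"`` uses the analytic reduction (the production path).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    lam0 = np.asarray(lam0_vec, dtype=float)
    qt, Kt = effective_rates_griffith(g1_state, params, literal_printed)
    m = float(g1_state[5])
    K, a, q = params["K"], params["a"], params["q"]
    if method == "quad":
        integral, _err = quad(
            lambda s: _last_stage(s, lam0, K, m, a, qt),
            0.0,
            t,
            epsabs=1e-10,
            epsrel=1e-10,
            limit=200,
        )
    elif method == "closed":
        integral = _int_hd(t, lam0, K, m, a, qt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(lam0.sum() + Kt * t - q * integral)


def survival_q_griffith(
    tau: float,
    lam0_vec: Sequence[float],
    g1_state: Sequence[float],
    params: Dict[str, float],
    method: str = "closed",
    literal_printed: bool = False,
) -> float:
    """No-G1-reaction survival probability for the Griffith model."""
    lam0 = np.asarray(lam0_vec, dtype=float)
    h = h_griffith(tau, lam0, g1_state, params, literal_printed)
    lam_t = lambda_griffith(
        tau, lam0, params["K"], float(g1_state[5]), params["a"], params["q"]
    )
    # sum h_i = sum_{i<d} lambda_i + h_d  (conversion stages are shared)
    h_sum = lam_t[:-1].sum() + h[-1]
    g = g_griffith(tau, lam0, g1_state, params, method, literal_printed)
    return math.exp(h_sum - g)


# ---------------------------------------------------------------------------
# Cascade state object + generic survival entry point
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoissonCascade:
    """Poisson parameters of the G2 distribution at a fixed G1 state.

    ``lam`` holds the current Poisson mean(s); ``s`` the promoter index and
    ``m`` the mRNA count that define the effective rates.  At a reset (right
    after a G1 event) ``h = lam`` and g carries the normalization that makes
    ``Q(0) = 1``.
    """

    model: str
    lam: np.ndarray
    s: int
    m: int
    params: Dict[str, float]

    def __post_init__(self):
        object.__setattr__(self, "lam", np.atleast_1d(np.asarray(self.lam, float)))
        if np.any(self.lam < 0):
            raise ValueError("Poisson means must be non-negative")

    def _g1_state(self):
        if self.model == "switch":
            onehot = [0, 0, 0]
            onehot[self.s] = 1
            return (*onehot, self.m)
        onehot = [0] * 5
        onehot[self.s] = 1
        return (*onehot, self.m)

    def effective_rates(self) -> Tuple[float, float]:
        if self.model == "switch":
            return effective_rates_switch(self._g1_state(), self.params)
        return effective_rates_griffith(self._g1_state(), self.params)

    def g1_coeffs(self) -> Tuple[float, float]:
        return g1_linear_coeffs(self.model, self.s, self.m, self.params)

    def b_coeffs(self) -> Tuple[float, float]:
        """(b1, b2) of the short-time expansion ln Q ~ -b1*tau + b2*tau^2/2.

        b1 is the G1 propensity sum with the repressor count replaced by its
        mean; b2 = -c1 * hdot(0) follows from d lnQ/dtau = -(c0 + c1 h).
        """
        c0, c1 = self.g1_coeffs()
        p = self.params
        qt, _ = self.effective_rates()
        lam_last = float(self.lam[-1])
        b1 = c0 + c1 * lam_last
        if self.model == "switch":
            hdot0 = p["K"] * self.m - qt * lam_last
        else:
            hdot0 = p["a"] * float(self.lam[-2]) - qt * lam_last
        return b1, -c1 * hdot0

    def advance(self, tau: float) -> "PoissonCascade":
        """Cascade after a G1-quiet interval of length tau (lambda(tau))."""
        p = self.params
        if self.model == "switch":
            lam_t = [lambda_switch(tau, float(self.lam[0]), p["K"], self.m, p["q"])]
        else:
            lam_t = lambda_griffith(tau, self.lam, p["K"], self.m, p["a"], p["q"])
        return replace(self, lam=np.asarray(lam_t))

    def log_survival(self, tau: float) -> float:
        p = self.params
        if self.model == "switch":
            h, g = h_g_switch(tau, float(self.lam[0]), self._g1_state(), p)
            return h - g
        return math.log(
            survival_q_griffith(tau, self.lam, self._g1_state(), p, method="closed")
        )

    def survival(self, tau: float) -> float:
        return math.exp(self.log_survival(tau))


def survival_Q(tau: float, cascade: PoissonCascade) -> float:
    """Survival function Q(tau) in (0, 1]; Q(0) = 1, monotone decreasing."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return cascade.survival(tau)


# ---------------------------------------------------------------------------
# Poisson inverse moments
# ---------------------------------------------------------------------------


def poisson_inverse_moment(a: float, lam: float) -> float:
    """Exact E[1/(n+a)] for n ~ Poisson(lam), a > 0.

    Evaluated by adaptive series summation centred on the Poisson mode (so
    that large means neither underflow nor need O(lam) leading terms whose
    weights are negligible); agrees analytically with the confluent
    ``B(a, lam)`` incomplete-gamma identity.
    """
    if a <= 0:
        raise ValueError("a must be positive (pole on the summation lattice)")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if lam == 0.0:
        return 1.0 / a
    n0 = int(lam)
    logw0 = -lam + n0 * math.log(lam) - math.lgamma(n0 + 1)
    w0 = math.exp(logw0)
    total = w0 / (n0 + a)
    # upward
    w = w0
    n = n0
    while True:
        n += 1
        w *= lam / n
        term = w / (n + a)
        total += term
        if term < 1e-17 * total and n > lam:
            break
    # downward
    w = w0
    n = n0
    while n > 0:
        w *= n / lam
        n -= 1
        term = w / (n + a)
        total += term
        if term < 1e-17 * total:
            break
    return total


def approx_inverse_moment(a: float, lam: float) -> float:
    """Three-term moment expansion of E[1/(n+a)] around the Poisson mean.

    ``1/(a+lam) + lam/(a+lam)^3 - lam/(a+lam)^4``.  Accurate for
    ``a + lam >> 1``; inaccurate when both ``lam`` and ``a`` are below ~1,
    which is why :func:`inverse_moment` falls back to the exact series
    there.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    c = a + lam
    return 1.0 / c + lam / c**3 - lam / c**4


def inverse_moment(a: float, lam: float, mode: str = "series") -> float:
    """Dispatch: ``mode="exact"`` always sums the series; ``mode="series"``
    uses the moment expansion with automatic exact fallback when ``a < 1``
    or ``lam < 1``."""
    if mode == "exact":
        return poisson_inverse_moment(a, lam)
    if mode == "series":
        if a < 1.0 or lam < 1.0:
            return poisson_inverse_moment(a, lam)
        return approx_inverse_moment(a, lam)
    raise ValueError(f"unknown inverse-moment mode {mode!r}")


# ---------------------------------------------------------------------------
# Fast waiting-time approximation
# ---------------------------------------------------------------------------


def fast_tau(
    xi1: float, b1: float, b2: float, eps: float = 1e-3
) -> Tuple[float, bool]:
    """First-order waiting time tau0 = ln(1/xi1)/b1 with its validity test.

    The correction ratio ``tau1/tau0 = (b2/b1)L/2 / (b1 - (b2/b1)L)``
    (L = ln(1/xi1)) estimates the relative error of tau0 against the
    quadratic expansion of ln Q; the fast path is accepted when
    ``|tau1/tau0| < eps``, otherwise the caller must solve Q(tau) = xi1
    exactly.  ``b1 <= 0`` forces the fallback.
    """
    if not 0.0 < xi1 < 1.0:
        raise ValueError("xi1 must lie in (0, 1)")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if b1 <= 0.0:
        return math.nan, False
    L = math.log(1.0 / xi1)
    tau0 = L / b1
    denom = b1 - (b2 / b1) * L
    if denom == 0.0:
        return tau0, False
    ratio = 0.5 * (b2 / b1) * L / denom
    return tau0, abs(ratio) < eps
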