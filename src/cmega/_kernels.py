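"""Compiled (numba) inner loops for ensemble production runs.

The pure-Python implementations in :mod:`cmega.ssa` and :mod:`cmega.hybrid`
define the semantics; these kernels repeat the same arithmetic in nopython
mode and consume random numbers in the same order, so a run driven by an
explicit uniform stream is bit-for-bit comparable between the two paths
(this equivalence is asserted in the test suite).

All kernels accept an optional uniform stream ``u``: when non-empty it is
consumed sequentially instead of the seeded generator (r1, r2 per SSA event;
xi1, xi2 per hybrid event).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STREAM_EXHAUSTED = 2
STATUS_ROOT_FAILURE = 3

_NO_EVENT = 1e300


# ---------------------------------------------------------------------------
# Exact SSA
# ---------------------------------------------------------------------------


@njit(cache=True)
def _propensities(term_rate, term_reactants, term_rxn, state, props):
    props[:] = 0.0
    for j in range(term_rate.shape[0]):
        v = term_rate[j]
        for o in range(term_reactants.shape[1]):
            sp = term_reactants[j, o]
            if sp >= 0:
                v *= state[sp]
        props[term_rxn[j]] += v
    total = 0.0
    for i in range(props.shape[0]):
        total += props[i]
    return total


@njit(cache=True)
def ssa_run(
    term_rate,
    term_reactants,
    term_rxn,
    stoich,
    g1_mask,
    init,
    t_final,
    grid,
    seed,
    u,
    out,
):
    """One SSA realization recorded on ``grid`` by zero-order hold."""
    nu = u.shape[0]
    if nu == 0:
        np.random.seed(seed)
    ui = 0
    n_rxn = stoich.shape[0]
    n_sp = stoich.shape[1]
    state = init.copy()
    props = np.empty(n_rxn)
    t = 0.0
    gi = 0
    T = grid.shape[0]
    n_events = 0
    while True:
        a0 = _propensities(term_rate, term_reactants, term_rxn, state, props)
        r2 = 0.0
        if a0 <= 0.0:
            tau = t_final - t + 1.0
        else:
            if nu > 0:
                if ui + 1 >= nu:
                    break
                r1 = u[ui]
                r2 = u[ui + 1]
                ui += 2
            else:
                r1 = np.random.random()
                r2 = np.random.random()
            if r1 <= 0.0:
                r1 = 1e-300
            tau = np.log(1.0 / r1) / a0
        t_next = t + tau
        while gi < T and grid[gi] < t_next:
            for i in range(n_sp):
                out[gi, i] = state[i]
            gi += 1
        if t_next >= t_final or a0 <= 0.0:
            break
        threshold = r2 * a0
        acc = 0.0
        mu = n_rxn - 1
        for j in range(n_rxn):
            acc += props[j]
            if acc > threshold:
                mu = j
                break
        for i in range(n_sp):
            state[i] += stoich[mu, i]
        t = t_next
        n_events += 1
    while gi < T:
        for i in range(n_sp):
            out[gi, i] = state[i]
        gi += 1
    return n_events


@njit(cache=True)
def ssa_first_g1(
    term_rate, term_reactants, term_rxn, stoich, g1_mask, init, horizon, seed
):
    """Time of the first G1 reaction, or -1.0 if none fires before horizon."""
    np.random.seed(seed)
    n_rxn = stoich.shape[0]
    n_sp = stoich.shape[1]
    state = init.copy()
    props = np.empty(n_rxn)
    t = 0.0
    while True:
        a0 = _propensities(term_rate, term_reactants, term_rxn, state, props)
        if a0 <= 0.0:
            return -1.0
        r1 = np.random.random()
        if r1 <= 0.0:
            r1 = 1e-300
        t += np.log(1.0 / r1) / a0
        if t >= horizon:
            return -1.0
        r2 = np.random.random()
        threshold = r2 * a0
        acc = 0.0
        mu = n_rxn - 1
        for j in range(n_rxn):
            acc += props[j]
            if acc > threshold:
                mu = j
                break
        if g1_mask[mu] == 1:
            return t
        for i in range(n_sp):
            state[i] += stoich[mu, i]


# ---------------------------------------------------------------------------
# Shared hybrid helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _inv_moment_exact(a, lam):
    if lam <= 0.0:
        return 1.0 / a
    n0 = int(lam)
    logw0 = -lam + n0 * np.log(lam) - math.lgamma(n0 + 1.0)
    w0 = np.exp(logw0)
    total = w0 / (n0 + a)
    w = w0
    n = n0
    while True:
        n += 1
        w *= lam / n
        term = w / (n + a)
        total += term
        if term < 1e-17 * total and n > lam:
            break
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


@njit(cache=True)
def _inv_moment(a, lam, exact):
    if exact or a < 1.0 or lam < 1.0:
        return _inv_moment_exact(a, lam)
    c = a + lam
    return 1.0 / c + lam / (c * c * c) - lam / (c * c * c * c)


@njit(cache=True)
def _i_poly(c, t, jmax, out):
    """out[j] = integral_0^t exp(-c*s) s^j ds, j = 0..jmax."""
    for j in range(jmax + 1):
        out[j] = 0.0
    if t <= 0.0:
        return
    x = c * t
    if x < jmax + 4.0 and x > -30.0:
        term = 1.0
        for kk in range(300):
            if kk > 0:
                term *= -x / kk
            mx = 0.0
            for j in range(jmax + 1):
                out[j] += term / (j + kk + 1.0)
                av = abs(out[j])
                if av > mx:
                    mx = av
            if abs(term) < 1e-18 * (1.0 + mx) and kk > abs(x):
                break
        tp = t
        for j in range(jmax + 1):
            out[j] *= tp
            tp *= t
        return
    if x <= -30.0:
        b = -c
        out[0] = np.expm1(b * t) / b
        tp = t
        ebt = np.exp(b * t)
        for j in range(1, jmax + 1):
            out[j] = (tp * ebt - j * out[j - 1]) / b
            tp *= t
        return
    out[0] = -np.expm1(-x) / c
    tp = t
    emx = np.exp(-x)
    for j in range(1, jmax + 1):
        out[j] = (j * out[j - 1] - tp * emx) / c
        tp *= t


# ---------------------------------------------------------------------------
# Genetic-switch hybrid
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sw_lam_adv(lam, dt, Km, q):
    tgt = Km / q
    return (lam - tgt) * np.exp(-q * dt) + tgt


@njit(cache=True)
def _sw_neg_lnQ(tau, lam0, Km, q, qt, Kt):
    """g(tau) - h(tau) = -ln Q(tau) for the switch."""
    h = (lam0 - Km / qt) * np.exp(-qt * tau) + Km / qt
    g = (
        (lam0 - Km / qt) * (q / qt) * (np.exp(-qt * tau) - 1.0)
        + (Kt - Km * q / qt) * tau
        + lam0
    )
    return g - h


@njit(cache=True)
def _sw_root(L, lam0, Km, q, qt, Kt, c0, c1, tau0):
    """Solve -ln Q(tau) = L by safeguarded Newton (relative tol 1e-12)."""
    lo = 0.0
    hi = tau0 if tau0 > 1e-12 else 1e-12
    n_dbl = 0
    while _sw_neg_lnQ(hi, lam0, Km, q, qt, Kt) < L:
        lo = hi
        hi *= 2.0
        n_dbl += 1
        if n_dbl > 400:
            return _NO_EVENT
    tau = tau0
    if tau <= lo or tau >= hi:
        tau = 0.5 * (lo + hi)
    for _ in range(200):
        f = _sw_neg_lnQ(tau, lam0, Km, q, qt, Kt) - L
        if f > 0.0:
            hi = tau
        else:
            lo = tau
        h = (lam0 - Km / qt) * np.exp(-qt * tau) + Km / qt
        fp = c0 + c1 * h
        step = f / fp if fp > 0.0 else 0.0
        new = tau - step
        if new <= lo or new >= hi:
            new = 0.5 * (lo + hi)
        if abs(new - tau) <= 1e-13 * (1.0 + tau):
            return new
        tau = new
    return tau


@njit(cache=True)
def hybrid_switch_run(
    alpha1,
    alpha2,
    beta1,
    beta2,
    r0,
    r,
    K,
    k,
    q,
    s0,
    m0,
    lam_init,
    t_final,
    grid,
    seed,
    eps,
    exact_mom,
    u,
    out_s,
    out_m,
    out_lam,
):
    nu = u.shape[0]
    if nu == 0:
        np.random.seed(seed)
    ui = 0
    s = s0
    m = m0
    lam = lam_init
    t = 0.0
    gi = 0
    T = grid.shape[0]
    n_events = 0
    n_fast = 0
    n_exact = 0
    status = STATUS_OK
    while True:
        if s == 0:
            c0 = r0 + k * m
            c1 = alpha1
        elif s == 1:
            c0 = beta1 + r0 + k * m
            c1 = alpha2
        else:
            c0 = beta2 + r + k * m
            c1 = 0.0
        qt = q + c1
        Km = K * m
        Kt = c0 + Km
        b1 = c0 + c1 * lam
        if b1 <= 0.0:
            tau = t_final - t + 1.0
        else:
            if nu > 0:
                if ui >= nu:
                    status = STATUS_STREAM_EXHAUSTED
                    break
                xi1 = u[ui]
                ui += 1
            else:
                xi1 = np.random.random()
            if xi1 <= 0.0:
                xi1 = 1e-300
            L = np.log(1.0 / xi1)
            tau0 = L / b1
            b2 = c1 * (qt * lam - Km)
            denom = b1 - (b2 / b1) * L
            fast = False
            if denom != 0.0:
                ratio = 0.5 * (b2 / b1) * L / denom
                if abs(ratio) < eps:
                    fast = True
            if fast:
                tau = tau0
                n_fast += 1
            else:
                tau = _sw_root(L, lam, Km, q, qt, Kt, c0, c1, tau0)
                n_exact += 1
                if tau >= _NO_EVENT:
                    tau = t_final - t + 1.0
        t_next = t + tau
        while gi < T and grid[gi] < t_next:
            dt = grid[gi] - t
            out_s[gi] = s
            out_m[gi] = m
            out_lam[gi] = _sw_lam_adv(lam, dt, Km, q)
            gi += 1
        if t_next >= t_final:
            break
        lam = _sw_lam_adv(lam, tau, Km, q)
        t = t_next
        if nu > 0:
            if ui >= nu:
                status = STATUS_STREAM_EXHAUSTED
                break
            xi2 = u[ui]
            ui += 1
        else:
            xi2 = np.random.random()
        # reaction probabilities in the model's 6-way grouping; within each
        # promoter state only three channels are open and the probabilities
        # sum to one identically (even with the approximate inverse moment).
        if s == 0:
            A = (r0 + k * m) / alpha1
            M = _inv_moment(A, lam, exact_mom)
            p_bind = 1.0 - A * M
            p_mid = (r0 / alpha1) * M  # transcription
            if xi2 < p_bind:
                s = 1
            elif xi2 < p_bind + p_mid:
                m += 1
            else:
                m -= 1
        elif s == 1:
            A = (beta1 + r0 + k * m) / alpha2
            M = _inv_moment(A, lam, exact_mom)
            p_bind = 1.0 - A * M
            p_unb = (beta1 / alpha2) * M
            p_tx = (r0 / alpha2) * M
            if xi2 < p_bind:
                s = 2
            elif xi2 < p_bind + p_unb:
                s = 0
            elif xi2 < p_bind + p_unb + p_tx:
                m += 1
            else:
                m -= 1
        else:
            tot = beta2 + r + k * m
            p_unb = beta2 / tot
            p_tx = r / tot
            if xi2 < p_unb:
                s = 1
            elif xi2 < p_unb + p_tx:
                m += 1
            else:
                m -= 1
        n_events += 1
    while gi < T:
        dt = grid[gi] - t
        out_s[gi] = s
        out_m[gi] = m
        out_lam[gi] = _sw_lam_adv(lam, dt, K * m, q)
        gi += 1
    return n_events, n_fast, n_exact, status


# ---------------------------------------------------------------------------
# Griffith hybrid
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gr_lam_adv(lam, tau, Km, a, decay, out, ibuf):
    """lambda(tau) (or h(tau) with decay=q_tilde) for the cascade."""
    d = lam.shape[0]
    Kma = Km / a
    e_at = np.exp(-a * tau)
    for i in range(d - 1):
        acc = 0.0
        atj = 1.0
        fact = 1.0
        for j in range(i + 1):
            if j > 0:
                atj *= a * tau
                fact *= j
            acc += (Kma - lam[i - j]) * atj / fact
        out[i] = Kma - e_at * acc
    tgt = Km / decay
    val = tgt + (lam[d - 1] - tgt) * np.exp(-decay * tau)
    _i_poly(a - decay, tau, d - 2, ibuf)
    ssum = 0.0
    apow = a
    fact = 1.0
    for j in range(d - 1):
        if j > 0:
            apow *= a
            fact *= j
        ssum += (apow / fact) * (Kma - lam[d - 2 - j]) * ibuf[j]
    out[d - 1] = val - np.exp(-decay * tau) * ssum
    for i in range(d):  # floor the ~1e-15 negatives from series cancellation
        if out[i] < 0.0:
            out[i] = 0.0


@njit(cache=True)
def _gr_int_hd(T, lam, Km, a, qt, ia, iaq):
    """integral_0^T h_d dt in closed form."""
    d = lam.shape[0]
    base = (Km / qt) * T + (lam[d - 1] - Km / qt) * (-np.expm1(-qt * T)) / qt
    _i_poly(a, T, d - 2, ia)
    _i_poly(a - qt, T, d - 2, iaq)
    eqT = np.exp(-qt * T)
    Kma = Km / a
    ssum = 0.0
    apow = a
    fact = 1.0
    for j in range(d - 1):
        if j > 0:
            apow *= a
            fact *= j
        ssum += (apow / fact) * (Kma - lam[d - 2 - j]) * (ia[j] - eqT * iaq[j]) / qt
    return base - ssum


@njit(cache=True)
def _gr_neg_lnQ_fp(tau, lam, lam_sum0, Km, a, q, qt, Kt, buf, ibuf, ia, iaq):
    """(-ln Q(tau), d(-lnQ)/dtau) for the Griffith cascade."""
    _gr_lam_adv(lam, tau, Km, a, qt, buf, ibuf)  # buf: lambda_{i<d} and h_d
    hd = buf[lam.shape[0] - 1]
    body = 0.0
    for i in range(lam.shape[0] - 1):
        body += buf[i]
    int_hd = _gr_int_hd(tau, lam, Km, a, qt, ia, iaq)
    neg_lnQ = lam_sum0 + Kt * tau - q * int_hd - body - hd
    c1 = qt - q
    c0 = Kt - Km
    return neg_lnQ, c0 + c1 * hd


@njit(cache=True)
def _gr_root(L, lam, lam_sum0, Km, a, q, qt, Kt, tau0, buf, ibuf, ia, iaq):
    lo = 0.0
    hi = tau0 if tau0 > 1e-12 else 1e-12
    n_dbl = 0
    while True:
        f, _ = _gr_neg_lnQ_fp(hi, lam, lam_sum0, Km, a, q, qt, Kt, buf, ibuf, ia, iaq)
        if f >= L:
            break
        lo = hi
        hi *= 2.0
        n_dbl += 1
        if n_dbl > 400:
            return _NO_EVENT
    tau = tau0
    if tau <= lo or tau >= hi:
        tau = 0.5 * (lo + hi)
    for _ in range(200):
        f, fp = _gr_neg_lnQ_fp(tau, lam, lam_sum0, Km, a, q, qt, Kt, buf, ibuf, ia, iaq)
        f -= L
        if f > 0.0:
            hi = tau
        else:
            lo = tau
        step = f / fp if fp > 0.0 else 0.0
        new = tau - step
        if new <= lo or new >= hi:
            new = 0.5 * (lo + hi)
        if abs(new - tau) <= 1e-13 * (1.0 + tau):
            return new
        tau = new
    return tau


@njit(cache=True)
def hybrid_griffith_run(
    alphas,
    betas,
    r,
    K,
    k,
    q,
    a,
    s0,
    m0,
    lam_init,
    t_final,
    grid,
    seed,
    eps,
    exact_mom,
    qt_literal,
    u,
    out_s,
    out_m,
    out_lam,
):
    nu = u.shape[0]
    if nu == 0:
        np.random.seed(seed)
    ui = 0
    d = lam_init.shape[0]
    s = s0
    m = m0
    lam = lam_init.copy()
    buf = np.empty(d)
    ibuf = np.empty(d)
    ia = np.empty(d)
    iaq = np.empty(d)
    t = 0.0
    gi = 0
    T = grid.shape[0]
    n_events = 0
    n_fast = 0
    n_exact = 0
    status = STATUS_OK
    while True:
        c0 = k * m
        if s == 0:
            c0 += r
        else:
            c0 += betas[s - 1]
        c1 = alphas[s] if s < 4 else 0.0
        qt = c1 if qt_literal else q + c1
        Km = K * m
        Kt = c0 + Km
        lam_sum0 = 0.0
        for i in range(d):
            lam_sum0 += lam[i]
        b1 = c0 + c1 * lam[d - 1]
        if b1 <= 0.0:
            tau = t_final - t + 1.0
        else:
            if nu > 0:
                if ui >= nu:
                    status = STATUS_STREAM_EXHAUSTED
                    break
                xi1 = u[ui]
                ui += 1
            else:
                xi1 = np.random.random()
            if xi1 <= 0.0:
                xi1 = 1e-300
            L = np.log(1.0 / xi1)
            tau0 = L / b1
            b2 = c1 * (qt * lam[d - 1] - a * lam[d - 2])
            denom = b1 - (b2 / b1) * L
            fast = False
            if denom != 0.0:
                ratio = 0.5 * (b2 / b1) * L / denom
                if abs(ratio) < eps:
                    fast = True
            if fast:
                tau = tau0
                n_fast += 1
            else:
                tau = _gr_root(
                    L, lam, lam_sum0, Km, a, q, qt, Kt, tau0, buf, ibuf, ia, iaq
                )
                n_exact += 1
                if tau >= _NO_EVENT:
                    tau = t_final - t + 1.0
        t_next = t + tau
        while gi < T and grid[gi] < t_next:
            dt = grid[gi] - t
            out_s[gi] = s
            out_m[gi] = m
            _gr_lam_adv(lam, dt, Km, a, q, buf, ibuf)
            for i in range(d):
                out_lam[gi, i] = buf[i]
            gi += 1
        if t_next >= t_final:
            break
        _gr_lam_adv(lam, tau, Km, a, q, buf, ibuf)
        for i in range(d):
            lam[i] = buf[i]
        t = t_next
        if nu > 0:
            if ui >= nu:
                status = STATUS_STREAM_EXHAUSTED
                break
            xi2 = u[ui]
            ui += 1
        else:
            xi2 = np.random.random()
        lam_d = lam[d - 1]
        if s < 4:
            A = c0 / c1
            M = _inv_moment(A, lam_d, exact_mom)
            p_bind = 1.0 - A * M
            if s == 0:
                p_mid = (r / c1) * M  # transcription
                if xi2 < p_bind:
                    s = 1
                elif xi2 < p_bind + p_mid:
                    m += 1
                else:
                    m -= 1
            else:
                p_unb = (betas[s - 1] / c1) * M
                if xi2 < p_bind:
                    s += 1
                elif xi2 < p_bind + p_unb:
                    s -= 1
                else:
                    m -= 1
        else:
            tot = betas[3] + k * m
            if xi2 < betas[3] / tot:
                s = 3
            else:
                m -= 1
        n_events += 1
    while gi < T:
        dt = grid[gi] - t
        out_s[gi] = s
        out_m[gi] = m
        _gr_lam_adv(lam, dt, K * m, a, q, buf, ibuf)
        for i in range(d):
            out_lam[gi, i] = buf[i]
        gi += 1
    return n_events, n_fast, n_exact, status
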