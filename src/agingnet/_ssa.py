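"""Event-driven stochastic simulation kernels (numba-compiled).

Internal module operating on raw coefficient arrays; the wrappers in
:mod:`agingnet.simulate` handle validation and dataclasses.

Between damage events the deficit vector is frozen, so every component hazard
is a monotone non-decreasing piecewise-polynomial function of age (the pieces
are separated by hinge zero-crossings, of which each component has at most
two).  Waiting times are therefore drawn *exactly* by hazard inversion:

  1. locate the hinge breakpoints on the current interval by bisection,
  2. integrate the total hazard segment-by-segment with Gauss-Legendre
     quadrature (order chosen so polynomial pieces are integrated exactly),
  3. when the accumulated integral crosses the Exp(1) draw, invert inside the
     segment with safeguarded Newton iteration to 1e-10 years.

A thinning (rejection) sampler over short windows, valid because every
hazard is monotone in age, is provided as an independent cross-check.

Randomness is a counter-based splitmix64 stream per (seed, stream id), so
individuals are reproducible independently of batch order.
"""

import numpy as np
from numba import njit

_U64 = np.uint64
_SM_GAMMA = _U64(0x9E3779B97F4A7C15)
_SM_M1 = _U64(0xBF58476D1CE4E5B9)
_SM_M2 = _U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53

ROOT_TOL = 1e-10      # years, waiting-time inversion
BREAK_TOL = 1e-8      # years, hinge breakpoints


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _SM_M1
    z = (z ^ (z >> _U64(27))) * _SM_M2
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _stream_state(seed, stream):
    return _mix64((_U64(seed) << _U64(32)) ^ _U64(stream) ^ _U64(0x5DEECE66D))


@njit(cache=True, inline="always")
def _next_uniform(st):
    """Uniform in [0, 1) from a 1-element uint64 state array."""
    st[0] = st[0] + _SM_GAMMA
    return float(_mix64(st[0]) >> _U64(11)) * _INV53


@njit(cache=True, inline="always")
def _poly(c, x):
    r = 0.0
    for k in range(c.shape[0] - 1, -1, -1):
        r = r * x + c[k]
    return r


@njit(cache=True, inline="always")
def _mu_eval(mu_i, t):
    # mu_i holds coefficients for orders 1..n_f; constant term is zero
    r = 0.0
    for k in range(mu_i.shape[0] - 1, -1, -1):
        r = r * t + mu_i[k]
    return r * t


@njit(cache=True, inline="always")
def _node_rate(t, ci, mu_i, gam_i):
    f = ci + _mu_eval(mu_i, t)
    if f < 0.0:
        f = 0.0
    g = _poly(gam_i, f)
    return g if g > 0.0 else 0.0


@njit(cache=True, inline="always")
def _mort_rate(t, bsum, alpha, eta):
    x = bsum + _poly(eta, t)
    if x < 0.0:
        x = 0.0
    g = _poly(alpha, x)
    return g if g > 0.0 else 0.0


@njit(cache=True)
def _total_rate(t, d, cvec, bsum, mu, gam, alpha, eta):
    tot = _mort_rate(t, bsum, alpha, eta)
    for i in range(d.shape[0]):
        if d[i] == 0:
            tot += _node_rate(t, cvec[i], mu[i], gam[i])
    return tot


@njit(cache=True)
def _collect_breaks(t0, t1, d, cvec, bsum, mu, gam, alpha, eta, out):
    """Hinge zero-crossings of every active hazard component on (t0, t1).

    Each component is monotone non-decreasing in t, so each hinge argument
    crosses zero at most once; crossings are bracketed and bisected.
    Returns the number of breakpoints written into ``out`` (unsorted).
    """
    nb = 0
    n = d.shape[0]
    for i in range(n):
        if d[i] != 0:
            continue
        v0 = cvec[i] + _mu_eval(mu[i], t0)
        v1 = cvec[i] + _mu_eval(mu[i], t1)
        if v0 < 0.0 and v1 > 0.0:
            lo, hi = t0, t1
            while hi - lo > BREAK_TOL:
                mid = 0.5 * (lo + hi)
                if cvec[i] + _mu_eval(mu[i], mid) < 0.0:
                    lo = mid
                else:
                    hi = mid
            out[nb] = hi
            nb += 1
        f0 = v0 if v0 > 0.0 else 0.0
        f1 = v1 if v1 > 0.0 else 0.0
        g0 = _poly(gam[i], f0)
        g1 = _poly(gam[i], f1)
        if g0 < 0.0 and g1 > 0.0:
            lo, hi = t0, t1
            while hi - lo > BREAK_TOL:
                mid = 0.5 * (lo + hi)
                fm = cvec[i] + _mu_eval(mu[i], mid)
                if fm < 0.0:
                    fm = 0.0
                if _poly(gam[i], fm) < 0.0:
                    lo = mid
                else:
                    hi = mid
            out[nb] = hi
            nb += 1
    # mortality component
    x0 = bsum + _poly(eta, t0)
    x1 = bsum + _poly(eta, t1)
    if x0 < 0.0 and x1 > 0.0:
        lo, hi = t0, t1
        while hi - lo > BREAK_TOL:
            mid = 0.5 * (lo + hi)
            if bsum + _poly(eta, mid) < 0.0:
                lo = mid
            else:
                hi = mid
        out[nb] = hi
        nb += 1
    xa = x0 if x0 > 0.0 else 0.0
    xb = x1 if x1 > 0.0 else 0.0
    if _poly(alpha, xa) < 0.0 and _poly(alpha, xb) > 0.0:
        lo, hi = t0, t1
        while hi - lo > BREAK_TOL:
            mid = 0.5 * (lo + hi)
            xm = bsum + _poly(eta, mid)
            if xm < 0.0:
                xm = 0.0
            if _poly(alpha, xm) < 0.0:
                lo = mid
            else:
                hi = mid
        out[nb] = hi
        nb += 1
    return nb


@njit(cache=True)
def _seg_integral(a, b, d, cvec, bsum, mu, gam, alpha, eta, xg, wg):
    """Integral of the total hazard over [a, b] (Gauss-Legendre on [0,1])."""
    h = b - a
    s = 0.0
    for k in range(xg.shape[0]):
        t = a + h * xg[k]
        s += wg[k] * _total_rate(t, d, cvec, bsum, mu, gam, alpha, eta)
    return s * h


@njit(cache=True)
def _draw_event_time(tcur, horizon, d, cvec, bsum, mu, gam, alpha, eta,
                     xg, wg, u, breaks):
    """Solve int_{tcur}^{T} Gamma_tot(s) ds = u for T; inf if beyond horizon."""
    nb = _collect_breaks(tcur, horizon, d, cvec, bsum, mu, gam, alpha, eta, breaks)
    bps = np.sort(breaks[:nb])
    acc = 0.0
    a = tcur
    for s in range(nb + 1):
        b = bps[s] if s < nb else horizon
        if b <= a:
            continue
        seg = _seg_integral(a, b, d, cvec, bsum, mu, gam, alpha, eta, xg, wg)
        if acc + seg >= u:
            target = u - acc
            lo = a
            hi = b
            x = a + (b - a) * (target / seg) if seg > 0.0 else 0.5 * (a + b)
            for _ in range(200):
                fx = _seg_integral(a, x, d, cvec, bsum, mu, gam, alpha, eta,
                                   xg, wg) - target
                if fx > 0.0:
                    hi = x
                else:
                    lo = x
                gx = _total_rate(x, d, cvec, bsum, mu, gam, alpha, eta)
                if gx > 0.0:
                    xn = x - fx / gx
                    if xn <= lo or xn >= hi:
                        xn = 0.5 * (lo + hi)
                else:
                    xn = 0.5 * (lo + hi)
                if abs(xn - x) < ROOT_TOL or hi - lo < ROOT_TOL:
                    return xn
                x = xn
            return x
        acc += seg
        a = b
    return np.inf


@njit(cache=True)
def _simulate_one(t0, d, horizon, W, mu, gam, beta, alpha, eta, xg, wg, st,
                  dmg_row):
    """One individual from (t0, d) until death or horizon.

    Mutates ``d`` and writes damage ages into ``dmg_row``; returns the death
    age, or inf if still alive at the horizon.
    """
    n = d.shape[0]
    cvec = np.empty(n)
    rates = np.empty(n)
    breaks = np.empty(2 * n + 2)
    tcur = t0
    while True:
        bsum = 0.0
        for i in range(n):
            acc = 0.0
            for j in range(n):
                if d[j] != 0:
                    acc += W[i, j]
            cvec[i] = acc
            if d[i] != 0:
                bsum += beta[i]
        u = -np.log(1.0 - _next_uniform(st))
        te = _draw_event_time(tcur, horizon, d, cvec, bsum, mu, gam, alpha,
                              eta, xg, wg, u, breaks)
        if not te < horizon:
            return np.inf
        tot = _mort_rate(te, bsum, alpha, eta)
        for i in range(n):
            if d[i] == 0:
                rates[i] = _node_rate(te, cvec[i], mu[i], gam[i])
                tot += rates[i]
            else:
                rates[i] = 0.0
        # event identity ~ instantaneous rates; node order first, mortality last
        r = _next_uniform(st) * tot
        pick = -1
        cum = 0.0
        for i in range(n):
            if d[i] == 0:
                cum += rates[i]
                if r < cum:
                    pick = i
                    break
        if pick < 0:
            return te  # mortality
        d[pick] = 1
        dmg_row[pick] = te
        tcur = te


@njit(cache=True)
def simulate_batch(t0s, d0s, horizons, W, mu, gam, beta, alpha, eta, xg, wg,
                   seed, streams):
    """Simulate a batch of individuals; returns (damage_ages, death_ages).

    ``damage_ages[p, i]`` is the age node i was damaged (t0 for initially
    damaged nodes, inf if never damaged); ``death_ages[p]`` is inf for
    individuals alive at their horizon ``horizons[p]``.  Individual p uses
    the splitmix64 stream (seed, streams[p]) and so is independent of batch
    order.
    """
    P, n = d0s.shape
    dmg = np.full((P, n), np.inf)
    death = np.empty(P)
    st = np.empty(1, np.uint64)
    d = np.empty(n, np.int8)
    for p in range(P):
        st[0] = _stream_state(seed, streams[p])
        for i in range(n):
            d[i] = d0s[p, i]
            if d0s[p, i] != 0:
                dmg[p, i] = t0s[p]
        death[p] = _simulate_one(t0s[p], d, horizons[p], W, mu, gam, beta,
                                 alpha, eta, xg, wg, st, dmg[p])
    return dmg, death


@njit(cache=True)
def _simulate_one_thinning(t0, d, horizon, W, mu, gam, beta, alpha, eta, st,
                           dmg_row, window):
    """Thinning cross-check: monotone hazards bounded by their window-end value."""
    n = d.shape[0]
    cvec = np.empty(n)
    rates = np.empty(n)
    tcur = t0
    while True:
        bsum = 0.0
        for i in range(n):
            acc = 0.0
            for j in range(n):
                if d[j] != 0:
                    acc += W[i, j]
            cvec[i] = acc
            if d[i] != 0:
                bsum += beta[i]
        # propose candidate times window by window
        te = -1.0
        t = tcur
        while True:
            wend = min(t + window, horizon)
            bound = _total_rate(wend, d, cvec, bsum, mu, gam, alpha, eta)
            if bound <= 0.0:
                t = wend
                if t >= horizon:
                    break
                continue
            tc = t - np.log(1.0 - _next_uniform(st)) / bound
            if tc > wend:
                t = wend
                if t >= horizon:
                    break
                continue
            if (_next_uniform(st) * bound
                    <= _total_rate(tc, d, cvec, bsum, mu, gam, alpha, eta)):
                te = tc
                break
            t = tc
        if te < 0.0:
            return np.inf
        tot = _mort_rate(te, bsum, alpha, eta)
        for i in range(n):
            if d[i] == 0:
                rates[i] = _node_rate(te, cvec[i], mu[i], gam[i])
                tot += rates[i]
            else:
                rates[i] = 0.0
        r = _next_uniform(st) * tot
        pick = -1
        cum = 0.0
        for i in range(n):
            if d[i] == 0:
                cum += rates[i]
                if r < cum:
                    pick = i
                    break
        if pick < 0:
            return te
        d[pick] = 1
        dmg_row[pick] = te
        tcur = te


@njit(cache=True)
def simulate_batch_thinning(t0s, d0s, horizons, W, mu, gam, beta, alpha, eta,
                            seed, streams, window):
    P, n = d0s.shape
    dmg = np.full((P, n), np.inf)
    death = np.empty(P)
    st = np.empty(1, np.uint64)
    d = np.empty(n, np.int8)
    for p in range(P):
        st[0] = _stream_state(seed, streams[p])
        for i in range(n):
            d[i] = d0s[p, i]
            if d0s[p, i] != 0:
                dmg[p, i] = t0s[p]
        death[p] = _simulate_one_thinning(t0s[p], d, horizons[p], W, mu, gam,
                                          beta, alpha, eta, st, dmg[p], window)
    return dmg, death


def gauss_legendre_01(max_degree: int):
    """Nodes/weights on [0, 1] exact for polynomials up to ``max_degree``."""
    k = max(4, max_degree // 2 + 1)
    x, w = np.polynomial.legendre.leggauss(k)
    return (0.5 * (x + 1.0)).copy(), (0.5 * w).copy()
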