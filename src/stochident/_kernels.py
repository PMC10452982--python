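"""Numba-compiled inner loops for trajectory generation and coupled pairs.

All kernels operate on the flat descriptor encoding produced by
``ReactionNetwork.encoded()``:

``kinds``  int64[M]   0 zeroth, 1 first, 2 second (distinct), 3 second (dimer),
                      4 rational repression p/(1 + x_reg^q)
``sp1``    int64[M]   first reactant index (regulator index for kind 4), -1 unused
``sp2``    int64[M]   second reactant index (kind 2 only), -1 unused
``ratep``  int64[M]   rate-parameter slot, -1 when the rate is a fixed constant
``expp``   int64[M]   exponent-parameter slot (kind 4 only), -1 unused
``ratec``  float64[M] fixed rate constant, used only where ``ratep`` is -1

States are carried as float64 molecule counts (exact for counts < 2^53);
jump kernels record them on the grid as int64.

Status codes returned by the jump kernels: 0 ok, 1 a random-variate stream was
exhausted (caller should extend it and re-run), 2 the event cap was hit,
3 a propensity became non-finite.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NEED_MORE = 1
STATUS_EVENT_CAP = 2
STATUS_NOT_FINITE = 3


@njit(cache=True)
def _pow0(x, q):
    # x^q with the count conventions: 0^0 = 1, 0^q = 0 for q > 0.
    # q < 0 at x = 0 is returned as 0 (guarded removable case, never hit by
    # the supported propensity forms at non-negative states).
    if x > 0.0:
        return x ** q
    if q == 0.0:
        return 1.0
    return 0.0


@njit(cache=True)
def props_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, out):
    M = kinds.shape[0]
    for j in range(M):
        k = ratec[j] if ratep[j] < 0 else c[ratep[j]]
        kd = kinds[j]
        if kd == 0:
            a = k
        elif kd == 1:
            a = k * x[sp1[j]]
        elif kd == 2:
            a = k * x[sp1[j]] * x[sp2[j]]
        elif kd == 3:
            xm = x[sp1[j]]
            a = 0.5 * k * xm * (xm - 1.0)
        else:
            a = k / (1.0 + _pow0(x[sp1[j]], c[expp[j]]))
        out[j] = a if a > 0.0 else 0.0


@njit(cache=True)
def prop_derivs_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, dstate, dparam):
    """Analytic d a_j / d x_i and d a_j / d c_p of the (unclamped) forms."""
    M = kinds.shape[0]
    dstate[:] = 0.0
    dparam[:] = 0.0
    for j in range(M):
        k = ratec[j] if ratep[j] < 0 else c[ratep[j]]
        kd = kinds[j]
        if kd == 0:
            if ratep[j] >= 0:
                dparam[j, ratep[j]] = 1.0
        elif kd == 1:
            dstate[j, sp1[j]] = k
            if ratep[j] >= 0:
                dparam[j, ratep[j]] = x[sp1[j]]
        elif kd == 2:
            dstate[j, sp1[j]] = k * x[sp2[j]]
            dstate[j, sp2[j]] = k * x[sp1[j]]
            if ratep[j] >= 0:
                dparam[j, ratep[j]] = x[sp1[j]] * x[sp2[j]]
        elif kd == 3:
            xm = x[sp1[j]]
            dstate[j, sp1[j]] = 0.5 * k * (2.0 * xm - 1.0)
            if ratep[j] >= 0:
                dparam[j, ratep[j]] = 0.5 * xm * (xm - 1.0)
        else:
            q = c[expp[j]]
            xv = x[sp1[j]]
            den = 1.0 + _pow0(xv, q)
            dstate[j, sp1[j]] = -k * q * _pow0(xv, q - 1.0) / (den * den)
            if ratep[j] >= 0:
                dparam[j, ratep[j]] = 1.0 / den
            if expp[j] >= 0:
                if xv > 0.0:
                    dparam[j, expp[j]] = -k * _pow0(xv, q) * np.log(xv) / (den * den)
                else:
                    # x^q ln x -> 0 as x -> 0+
                    dparam[j, expp[j]] = 0.0


@njit(cache=True)
def ssa_kernel(kinds, sp1, sp2, ratep, expp, ratec, nu, c, x0, grid, u, max_events):
    """Gillespie direct method consuming uniforms (eta1, eta2 per event) from ``u``.

    The state recorded at a grid point reflects every event with time <= t_l.
    Returns (states, n_events, n_uniforms_used, status).
    """
    N = x0.shape[0]
    M = kinds.shape[0]
    L = grid.shape[0]
    states = np.zeros((L, N), np.int64)
    x = x0.astype(np.float64)
    a = np.empty(M, np.float64)
    t = 0.0
    gi = 0
    ptr = 0
    nev = 0
    while True:
        props_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, a)
        a0 = 0.0
        for j in range(M):
            if not np.isfinite(a[j]):
                return states, nev, ptr, STATUS_NOT_FINITE
            a0 += a[j]
        if a0 <= 0.0:
            break  # absorbing state: frozen for the rest of the horizon
        if ptr + 2 > u.shape[0]:
            return states, nev, ptr, STATUS_NEED_MORE
        u1 = u[ptr]
        u2 = u[ptr + 1]
        ptr += 2
        tnew = t - np.log(u1) / a0
        while gi < L and grid[gi] < tnew:
            for i in range(N):
                states[gi, i] = np.int64(x[i] + 0.5)
            gi += 1
        if gi >= L:
            break  # next event falls beyond the horizon
        thr = u2 * a0
        acc = 0.0
        jstar = M - 1
        for j in range(M):
            acc += a[j]
            if acc > thr:
                jstar = j
                break
        for i in range(N):
            x[i] += nu[i, jstar]
        t = tnew
        nev += 1
        if nev >= max_events:
            return states, nev, ptr, STATUS_EVENT_CAP
    while gi < L:
        for i in range(N):
            states[gi, i] = np.int64(x[i] + 0.5)
        gi += 1
    return states, nev, ptr, STATUS_OK


@njit(cache=True)
def rtc_kernel(kinds, sp1, sp2, ratep, expp, ratec, nu, c, x0, grid, E, caps,
               max_events):
    """Random-time-change (modified next reaction) simulation.

    ``E[j, :caps[j]]`` holds the unit-rate exponential increments of the j-th
    reaction's internal Poisson clock. Returns
    (states, n_events, counts_used, status, exhausted_stream).
    """
    N = x0.shape[0]
    M = kinds.shape[0]
    L = grid.shape[0]
    states = np.zeros((L, N), np.int64)
    x = x0.astype(np.float64)
    a = np.empty(M, np.float64)
    Tint = np.zeros(M, np.float64)
    Pnext = np.empty(M, np.float64)
    idx = np.zeros(M, np.int64)
    for j in range(M):
        Pnext[j] = E[j, 0]
    t = 0.0
    gi = 0
    nev = 0
    while True:
        props_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, a)
        tau = np.inf
        jstar = -1
        for j in range(M):
            if not np.isfinite(a[j]):
                return states, nev, idx + 1, STATUS_NOT_FINITE, -1
            if a[j] > 0.0:
                dtj = (Pnext[j] - Tint[j]) / a[j]
                if dtj < tau:
                    tau = dtj
                    jstar = j
        if jstar < 0:
            break  # absorbing state
        tnew = t + tau
        while gi < L and grid[gi] < tnew:
            for i in range(N):
                states[gi, i] = np.int64(x[i] + 0.5)
            gi += 1
        if gi >= L:
            break
        for j in range(M):
            Tint[j] += a[j] * tau
        for i in range(N):
            x[i] += nu[i, jstar]
        idx[jstar] += 1
        if idx[jstar] >= caps[jstar]:
            return states, nev, idx + 1, STATUS_NEED_MORE, jstar
        Pnext[jstar] += E[jstar, idx[jstar]]
        t = tnew
        nev += 1
        if nev >= max_events:
            return states, nev, idx + 1, STATUS_EVENT_CAP, -1
    while gi < L:
        for i in range(N):
            states[gi, i] = np.int64(x[i] + 0.5)
        gi += 1
    return states, nev, idx + 1, STATUS_OK, -1


@njit(cache=True)
def cfd_kernel(kinds, sp1, sp2, ratep, expp, ratec, nu, c, cp, x0, grid, E, caps,
               max_events):
    """Coupled pair (X, X') as one jump process with 3 channels per reaction.

    Channel (j,0) fires reaction j in both paths at rate min(a_j, a_j');
    (j,1) fires only the unperturbed path at rate a_j - min; (j,2) fires only
    the perturbed path at rate a_j' - min. ``E[3*j+d]`` are independent
    unit-rate exponential streams. All 3M rates are recomputed after every
    firing. Returns (states, states_pert, n_events, counts_used, status,
    exhausted_stream).
    """
    N = x0.shape[0]
    M = kinds.shape[0]
    L = grid.shape[0]
    nch = 3 * M
    states = np.zeros((L, N), np.int64)
    statesp = np.zeros((L, N), np.int64)
    x = x0.astype(np.float64)
    xp = x0.astype(np.float64)
    a = np.empty(M, np.float64)
    ap = np.empty(M, np.float64)
    b = np.empty(nch, np.float64)
    Tint = np.zeros(nch, np.float64)
    Pnext = np.empty(nch, np.float64)
    idx = np.zeros(nch, np.int64)
    for ch in range(nch):
        Pnext[ch] = E[ch, 0]
    t = 0.0
    gi = 0
    nev = 0
    while True:
        props_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, a)
        props_kernel(kinds, sp1, sp2, ratep, expp, ratec, xp, cp, ap)
        for j in range(M):
            if not (np.isfinite(a[j]) and np.isfinite(ap[j])):
                return states, statesp, nev, idx + 1, STATUS_NOT_FINITE, -1
            m = a[j] if a[j] < ap[j] else ap[j]
            b[3 * j] = m
            b[3 * j + 1] = a[j] - m
            b[3 * j + 2] = ap[j] - m
        tau = np.inf
        chstar = -1
        for ch in range(nch):
            if b[ch] > 0.0:
                dtc = (Pnext[ch] - Tint[ch]) / b[ch]
                if dtc < tau:
                    tau = dtc
                    chstar = ch
        if chstar < 0:
            break  # both paths absorbed
        tnew = t + tau
        while gi < L and grid[gi] < tnew:
            for i in range(N):
                states[gi, i] = np.int64(x[i] + 0.5)
                statesp[gi, i] = np.int64(xp[i] + 0.5)
            gi += 1
        if gi >= L:
            break
        for ch in range(nch):
            Tint[ch] += b[ch] * tau
        j = chstar // 3
        d = chstar - 3 * j
        if d != 2:
            for i in range(N):
                x[i] += nu[i, j]
        if d != 1:
            for i in range(N):
                xp[i] += nu[i, j]
        idx[chstar] += 1
        if idx[chstar] >= caps[chstar]:
            return states, statesp, nev, idx + 1, STATUS_NEED_MORE, chstar
        Pnext[chstar] += E[chstar, idx[chstar]]
        t = tnew
        nev += 1
        if nev >= max_events:
            return states, statesp, nev, idx + 1, STATUS_EVENT_CAP, -1
    while gi < L:
        for i in range(N):
            states[gi, i] = np.int64(x[i] + 0.5)
            statesp[gi, i] = np.int64(xp[i] + 0.5)
        gi += 1
    return states, statesp, nev, idx + 1, STATUS_OK, -1


@njit(cache=True)
def cle_kernel(kinds, sp1, sp2, ratep, expp, ratec, nuf, c, x0, grid, dt, seed):
    """Euler-Maruyama path of the diffusion approximation on the grid.

    Propensities are clamped at 0 before entering drift and sqrt diffusion
    (which also freezes noise at absorbing boundaries); the state itself is
    left unclamped so that linear-system means stay exact and conservation
    laws hold pathwise. The last sub-step of each grid interval is shortened
    to land exactly on the grid point.
    """
    np.random.seed(seed)
    N = x0.shape[0]
    M = kinds.shape[0]
    L = grid.shape[0]
    states = np.zeros((L, N), np.float64)
    x = x0.copy()
    a = np.empty(M, np.float64)
    t = 0.0
    for gi in range(L):
        tg = grid[gi]
        while t < tg - 1e-12:
            h = dt if t + dt <= tg else tg - t
            props_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, a)
            sh = np.sqrt(h)
            for j in range(M):
                dW = sh * np.random.normal()
                inc = a[j] * h + np.sqrt(a[j]) * dW
                for i in range(N):
                    x[i] += nuf[i, j] * inc
            t += h
        for i in range(N):
            states[gi, i] = x[i]
    return states


@njit(cache=True)
def cle_pathwise_kernel(kinds, sp1, sp2, ratep, expp, ratec, nuf, c, x0, grid,
                        dt, seed, P):
    """Joint Euler-Maruyama step of (X, dX/dc) for one diffusion path.

    The sensitivity diffusion coefficient (1/(2 sqrt(a_j))) (da_j/dX S + da_j/dc)
    is set to 0 where a_j = 0 (removable under clamping). Returns
    (states L x N, sens L x N x P).
    """
    np.random.seed(seed)
    N = x0.shape[0]
    M = kinds.shape[0]
    L = grid.shape[0]
    states = np.zeros((L, N), np.float64)
    sens = np.zeros((L, N, P), np.float64)
    x = x0.copy()
    S = np.zeros((N, P), np.float64)
    a = np.empty(M, np.float64)
    ds = np.empty((M, N), np.float64)
    dp = np.empty((M, P), np.float64)
    G = np.empty((M, P), np.float64)
    t = 0.0
    for gi in range(L):
        tg = grid[gi]
        while t < tg - 1e-12:
            h = dt if t + dt <= tg else tg - t
            props_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, a)
            prop_derivs_kernel(kinds, sp1, sp2, ratep, expp, ratec, x, c, ds, dp)
            # G_j = da_j/dX S + da_j/dc, evaluated at the step start
            for j in range(M):
                for p in range(P):
                    gp = dp[j, p]
                    for i in range(N):
                        gp += ds[j, i] * S[i, p]
                    G[j, p] = gp
            sh = np.sqrt(h)
            for j in range(M):
                dW = sh * np.random.normal()
                inc = a[j] * h + np.sqrt(a[j]) * dW
                dfac = h
                if a[j] > 0.0:
                    dfac = h + dW / (2.0 * np.sqrt(a[j]))
                for i in range(N):
                    x[i] += nuf[i, j] * inc
                    for p in range(P):
                        S[i, p] += nuf[i, j] * G[j, p] * dfac
            t += h
        for i in range(N):
            states[gi, i] = x[i]
            for p in range(P):
                sens[gi, i, p] = S[i, p]
    return states, sens
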