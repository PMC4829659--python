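"""Numba kernels for the state-dependent speciation/extinction likelihood.

Per-branch ODE system for a k-state model (E_i: probability a lineage in
state i at time t before the present leaves no sampled descendants; D_i:
density of the observed subtending data):

    dE_i/dt = mu_i - (lam_i + mu_i + sum_j q_ij) E_i + lam_i E_i^2
              + sum_{j!=i} q_ij E_j
    dD_i/dt = -(lam_i + mu_i + sum_j q_ij) D_i + 2 lam_i E_i D_i
              + sum_{j!=i} q_ij D_j

integrated tipward -> rootward with an adaptive embedded Cash-Karp
Runge-Kutta 4(5) pair.  D is rescaled at every node join (and mid-branch on
underflow), accumulating the log factor, so the computation is stable for
large trees.
"""

import numpy as np
from numba import njit

# status codes
OK = 0
STEP_UNDERFLOW = 1
E_OUT_OF_BOUNDS = 2
ZERO_LIKELIHOOD = 3  # data impossible: log-likelihood is -inf (not an error)

_E_TOL = 1e-8  # permitted numerical excursion of E outside [0, 1]

# Cash-Karp tableau
_A2 = 1.0 / 5.0
_A3 = (3.0 / 40.0, 9.0 / 40.0)
_A4 = (3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0)
_A5 = (-11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0)
_A6 = (1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
       44275.0 / 110592.0, 253.0 / 4096.0)
_B5 = (37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0, 512.0 / 1771.0)
_B4 = (2825.0 / 27648.0, 0.0, 18575.0 / 48384.0, 13525.0 / 55296.0,
       277.0 / 14336.0, 1.0 / 4.0)


@njit(cache=False, fastmath=True)
def _deriv(y, lam, mu, q, qrow, k, out):
    for i in range(k):
        sE = 0.0
        sD = 0.0
        for j in range(k):
            if j != i:
                sE += q[i, j] * y[j]
                sD += q[i, j] * y[k + j]
        tot = lam[i] + mu[i] + qrow[i]
        E = y[i]
        out[i] = mu[i] - tot * E + lam[i] * E * E + sE
        out[k + i] = -tot * y[k + i] + 2.0 * lam[i] * E * y[k + i] + sD



@njit(cache=False, fastmath=True)
def _integrate_branch(y, t, lam, mu, q, qrow, k, rtol, atol, scratch):
    """Advance y=(E, D) over duration t in place.

    ``scratch`` is a preallocated (8, 2k) work array (stage derivatives and
    trial states), so repeated branch calls allocate nothing.
    Returns (log_compensation, status)."""
    if t <= 0.0:
        return 0.0, OK
    n2 = 2 * k
    k1 = scratch[0]
    k2 = scratch[1]
    k3 = scratch[2]
    k4 = scratch[3]
    k5 = scratch[4]
    k6 = scratch[5]
    ytmp = scratch[6]
    y5 = scratch[7]
    logcomp = 0.0

    # initial step: conservative fraction of branch and of the fastest scale
    ratemax = 0.0
    for i in range(k):
        r = lam[i] + mu[i] + qrow[i]
        if r > ratemax:
            ratemax = r
    h = t
    if ratemax > 0.0 and 0.1 / ratemax < h:
        h = 0.1 / ratemax
    s = 0.0
    hmin = max(t * 1e-14, 1e-300)
    while s < t:
        if h > t - s:
            h = t - s
        _deriv(y, lam, mu, q, qrow, k, k1)
        for i in range(n2):
            ytmp[i] = y[i] + h * _A2 * k1[i]
        _deriv(ytmp, lam, mu, q, qrow, k, k2)
        for i in range(n2):
            ytmp[i] = y[i] + h * (_A3[0] * k1[i] + _A3[1] * k2[i])
        _deriv(ytmp, lam, mu, q, qrow, k, k3)
        for i in range(n2):
            ytmp[i] = y[i] + h * (_A4[0] * k1[i] + _A4[1] * k2[i] + _A4[2] * k3[i])
        _deriv(ytmp, lam, mu, q, qrow, k, k4)
        for i in range(n2):
            ytmp[i] = y[i] + h * (_A5[0] * k1[i] + _A5[1] * k2[i]
                                  + _A5[2] * k3[i] + _A5[3] * k4[i])
        _deriv(ytmp, lam, mu, q, qrow, k, k5)
        for i in range(n2):
            ytmp[i] = y[i] + h * (_A6[0] * k1[i] + _A6[1] * k2[i] + _A6[2] * k3[i]
                                  + _A6[3] * k4[i] + _A6[4] * k5[i])
        _deriv(ytmp, lam, mu, q, qrow, k, k6)
        errnorm = 0.0
        for i in range(n2):
            y5i = y[i] + h * (_B5[0] * k1[i] + _B5[2] * k3[i]
                              + _B5[3] * k4[i] + _B5[5] * k6[i])
            y4i = y[i] + h * (_B4[0] * k1[i] + _B4[2] * k3[i] + _B4[3] * k4[i]
                              + _B4[4] * k5[i] + _B4[5] * k6[i])
            y5[i] = y5i
            sc = atol + rtol * (abs(y[i]) if abs(y[i]) > abs(y5i) else abs(y5i))
            e = abs(y5i - y4i) / sc
            if e > errnorm:
                errnorm = e
        if errnorm <= 1.0:
            s += h
            if t - s <= 1e-12 * t:
                s = t  # done: avoid a sliver step from float rounding
            for i in range(n2):
                y[i] = y5[i]
            # E must remain a probability (allow roundoff at the solver's
            # own error scale; anything larger is a genuine failure)
            etol = _E_TOL if _E_TOL > 100.0 * atol else 100.0 * atol
            for i in range(k):
                if y[i] < -etol or y[i] > 1.0 + etol:
                    return logcomp, E_OUT_OF_BOUNDS
            # mid-branch underflow compensation on D
            dmax = 0.0
            for i in range(k):
                if y[k + i] > dmax:
                    dmax = y[k + i]
            if 0.0 < dmax < 1e-150:
                for i in range(k):
                    y[k + i] /= dmax
                logcomp += np.log(dmax)
            fac = 5.0
            if errnorm > 1e-30:
                fac = 0.9 * errnorm ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
            h *= fac
        else:
            fac = 0.9 * errnorm ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            h *= fac
        if s < t and h < hmin:
            return logcomp, STEP_UNDERFLOW
    return logcomp, OK


@njit(cache=False, fastmath=True)
def musse_loglik_kernel(left, right, blen, tipstate, lam, mu, q, f,
                        rtol, atol, root_mode, condition, root_weights):
    """Pruning likelihood over a postorder-numbered tree.

    root_mode: 0 = weights proportional to root D, 1 = equal, 2 = given.
    Returns (loglik, status)."""
    n = left.shape[0]
    k = lam.shape[0]
    qrow = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if j != i:
                qrow[i] += q[i, j]
    y = np.empty(2 * k)
    scratch = np.empty((8, 2 * k))
    E = np.empty((n, k))
    D = np.empty((n, k))
    logcomp = 0.0
    for nd in range(n):
        if left[nd] < 0:
            st = tipstate[nd]
            for i in range(k):
                E[nd, i] = 1.0 - f[i]
                if st < 0:
                    D[nd, i] = f[i]
                else:
                    D[nd, i] = f[i] if i == st else 0.0
        else:
            l = left[nd]
            r = right[nd]
            dmax = 0.0
            for i in range(k):
                E[nd, i] = E[l, i]
                D[nd, i] = lam[i] * D[l, i] * D[r, i]
                if D[nd, i] > dmax:
                    dmax = D[nd, i]
            if dmax <= 0.0:
                return -np.inf, ZERO_LIKELIHOOD
            for i in range(k):
                D[nd, i] /= dmax
            logcomp += np.log(dmax)
        if nd < n - 1 and blen[nd] > 0.0:
            for i in range(k):
                y[i] = E[nd, i]
                y[k + i] = D[nd, i]
            lc, status = _integrate_branch(y, blen[nd], lam, mu, q, qrow,
                                           k, rtol, atol, scratch)
            logcomp += lc
            if status != OK:
                return np.nan, status
            for i in range(k):
                E[nd, i] = y[i]
                D[nd, i] = y[k + i]

    root = n - 1
    d = np.empty(k)
    for i in range(k):
        d[i] = D[root, i]
    if condition:
        for i in range(k):
            om = 1.0 - E[root, i]
            denom = lam[i] * om * om
            if denom > 0.0:
                d[i] /= denom
            else:
                d[i] = 0.0
    tot = 0.0
    wsum = 0.0
    for i in range(k):
        w = d[i] if root_mode == 0 else (1.0 / k if root_mode == 1 else root_weights[i])
        wsum += w
        tot += w * d[i]
    if wsum <= 0.0 or tot <= 0.0:
        return -np.inf, ZERO_LIKELIHOOD
    return np.log(tot / wsum) + logcomp, OK
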