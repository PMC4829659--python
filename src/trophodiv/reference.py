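"""Brute-force and closed-form reference implementations.

These exist to validate the production likelihood path and are deliberately
written along different routes:

* :func:`musse_loglik_rk4` — fixed-step classic Runge-Kutta 4 integration of
  the (E, D) system, no adaptivity, no mid-branch compensation logic beyond
  node rescaling;
* :func:`bd_loglik_closed_form` — the constant-rate birth-death likelihood
  from its closed-form E(t)/D(t) solutions on an ultrametric tree;
* :func:`mk_loglik_expm` — pruning likelihood of a neutral discrete (Mk)
  character using matrix exponentials per branch.

With state-independent lambda and mu, the k-state SSE log-likelihood equals
the birth-death log-likelihood plus the Mk log-likelihood (the E system
decouples from the character), which the test suite exploits.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import expm

from .likelihood import LikelihoodOptions, MusseParameters
from .trees import Phylogeny, TipStateMap

__all__ = ["musse_loglik_rk4", "bd_loglik_closed_form", "mk_loglik_expm"]


@njit(cache=False)
def _rk4_branch(y, t, h, lam, mu, q, k):
    """Classic RK4 with fixed step h over duration t (last step shortened)."""
    n2 = 2 * k
    qrow = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if j != i:
                qrow[i] += q[i, j]

    def f(yy, out):
        for i in range(k):
            sE = 0.0
            sD = 0.0
            for j in range(k):
                if j != i:
                    sE += q[i, j] * yy[j]
                    sD += q[i, j] * yy[k + j]
            tot = lam[i] + mu[i] + qrow[i]
            out[i] = mu[i] - tot * yy[i] + lam[i] * yy[i] * yy[i] + sE
            out[k + i] = -tot * yy[k + i] + 2.0 * lam[i] * yy[i] * yy[k + i] + sD

    k1 = np.empty(n2)
    k2 = np.empty(n2)
    k3 = np.empty(n2)
    k4 = np.empty(n2)
    tmp = np.empty(n2)
    s = 0.0
    while s < t - 1e-15 * t:
        step = h if s + h <= t else t - s
        f(y, k1)
        for i in range(n2):
            tmp[i] = y[i] + 0.5 * step * k1[i]
        f(tmp, k2)
        for i in range(n2):
            tmp[i] = y[i] + 0.5 * step * k2[i]
        f(tmp, k3)
        for i in range(n2):
            tmp[i] = y[i] + step * k3[i]
        f(tmp, k4)
        for i in range(n2):
            y[i] += step / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        s += step
    return y


def musse_loglik_rk4(tree: Phylogeny, states: TipStateMap, p: MusseParameters,
                     step: float = 1e-4,
                     opts: LikelihoodOptions = LikelihoodOptions()) -> float:
    """Fixed-step RK4 brute-force evaluation of the SSE pruning likelihood."""
    tipstate = states.encode(tree)
    k = p.k
    n = tree.n_nodes
    E = np.zeros((n, k))
    D = np.zeros((n, k))
    logcomp = 0.0
    for nd in range(n):
        if tree.left[nd] < 0:
            st = tipstate[nd]
            E[nd] = 1.0 - p.f
            D[nd] = p.f if st < 0 else np.where(np.arange(k) == st, p.f, 0.0)
        else:
            l, r = tree.left[nd], tree.right[nd]
            E[nd] = E[l]
            D[nd] = p.lam * D[l] * D[r]
            m = D[nd].max()
            if m <= 0:
                return -np.inf
            D[nd] /= m
            logcomp += np.log(m)
        if nd < n - 1 and tree.blen[nd] > 0:
            y = np.concatenate([E[nd], D[nd]])
            y = _rk4_branch(y, float(tree.blen[nd]), step, p.lam, p.mu, p.q, k)
            E[nd], D[nd] = y[:k], y[k:]
    d = D[n - 1].copy()
    if opts.condition_on_survival:
        denom = p.lam * (1.0 - E[n - 1]) ** 2
        d = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    if opts.root_mode == "obs":
        w = d
    elif opts.root_mode == "equal":
        w = np.ones(k)
    else:
        w = np.asarray(opts.root_weights, dtype=float)
    if w.sum() <= 0 or (w * d).sum() <= 0:
        return -np.inf
    return float(np.log((w * d).sum() / w.sum()) + logcomp)


def _bd_E(t, lam, mu):
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, 1.0):
        return lam * t / (1.0 + lam * t)
    ert = np.exp(r * t)
    return mu * (ert - 1.0) / (lam * ert - mu)


def _bd_logDtilde(t, lam, mu):
    """log of the tip-initialized D(t) solution e^{-rt} (1-E(t))^2."""
    r = lam - mu
    if abs(r) < 1e-12 * max(lam, 1.0):
        return -2.0 * np.log1p(lam * t)
    return -r * t + 2.0 * np.log1p(-_bd_E(t, lam, mu))


def bd_loglik_closed_form(tree: Phylogeny, lam: float, mu: float,
                          condition_on_survival: bool = True) -> float:
    """Constant-rate birth-death log-likelihood on an ultrametric tree.

    Uses the closed-form single-state solutions: along a branch the D
    equation is linear and homogeneous given E(t), so each branch contributes
    log Dt(age_top) - log Dt(age_bottom) where Dt is the tip-initialized
    solution; every internal node contributes log lambda; conditioning on
    survival subtracts log[lambda (1 - E(T))^2] at the root age T.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not tree.is_ultrametric(rel_tol=1e-6):
        raise ValueError("closed form requires an ultrametric tree")
    depth = tree.node_depths()
    height = depth[tree.tip_indices].max()
    age = height - depth  # time before present
    ll = 0.0
    n = tree.n_nodes
    for nd in range(n - 1):  # every non-root node has a branch above it
        ll += _bd_logDtilde(age[nd] + tree.blen[nd], lam, mu) - _bd_logDtilde(age[nd], lam, mu)
    n_internal = int(np.sum(tree.left >= 0))
    ll += n_internal * np.log(lam)
    if condition_on_survival:
        ll -= np.log(lam) + 2.0 * np.log1p(-_bd_E(age[n - 1], lam, mu))
    return float(ll)


def mk_loglik_expm(tree: Phylogeny, states: TipStateMap, q: np.ndarray,
                   root_mode: str = "obs") -> float:
    """Pruning likelihood of a neutral k-state Markov character.

    ``q`` holds off-diagonal transition rates; the generator's diagonal is
    set to minus the row sums.  Branch transition probabilities come from
    scipy's matrix exponential; the root is aggregated with weights
    proportional to the root partial likelihoods ('obs') or equally.
    """
    q = np.asarray(q, dtype=float).copy()
    k = q.shape[0]
    np.fill_diagonal(q, 0.0)
    gen = q - np.diag(q.sum(axis=1))
    tipstate = states.encode(tree)
    n = tree.n_nodes
    D = np.zeros((n, k))
    logcomp = 0.0
    for nd in range(n):
        if tree.left[nd] < 0:
            st = tipstate[nd]
            D[nd] = np.ones(k) if st < 0 else np.where(np.arange(k) == st, 1.0, 0.0)
        else:
            l, r = tree.left[nd], tree.right[nd]
            D[nd] = D[l] * D[r]
            m = D[nd].max()
            if m <= 0:
                return -np.inf
            D[nd] /= m
            logcomp += np.log(m)
        if nd < n - 1 and tree.blen[nd] > 0:
            P = expm(gen * float(tree.blen[nd]))
            D[nd] = P @ D[nd]
    d = D[n - 1]
    w = d if root_mode == "obs" else np.ones(k)
    if w.sum() <= 0:
        return -np.inf
    return float(np.log((w * d).sum() / w.sum()) + logcomp)
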