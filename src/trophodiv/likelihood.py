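"""Exact MuSSE log-likelihood on a phylogeny with discrete tip states.

A k-state model assigns each state its own speciation rate lambda_i and
extinction rate mu_i, with Markov transitions q_ij between states along
branches.  The likelihood is evaluated by integrating the standard coupled
(E, D) ODE system along every branch (tipward to rootward) and combining
daughter solutions at each node with the speciation density, in postorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from . import _musse_core as core
from .trees import Phylogeny, TipStateMap, TreeError

__all__ = [
    "MusseParameters",
    "LikelihoodOptions",
    "OdeState",
    "SolverError",
    "branch_integrate",
    "musse_loglik",
    "parameter_count",
]

_ROOT_MODES = {"obs": 0, "equal": 1, "given": 2}


class SolverError(RuntimeError):
    """ODE integration failed to meet tolerances (never silently clamped)."""


@dataclass
class MusseParameters:
    """Per-state rates of a k-state speciation/extinction model.

    ``q`` is a full k x k matrix whose off-diagonal entry q[i, j] is the
    transition rate from state i to state j; the diagonal is ignored.
    ``f`` holds per-state sampling fractions in (0, 1], default 1.
    """

    lam: np.ndarray
    mu: np.ndarray
    q: np.ndarray
    f: Optional[np.ndarray] = None

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        k = self.lam.shape[0]
        self.q = np.asarray(self.q, dtype=float).reshape(k, k).copy()
        np.fill_diagonal(self.q, 0.0)
        if self.f is None:
            self.f = np.ones(k)
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if self.mu.shape != (k,) or self.f.shape != (k,):
            raise ValueError("lam, mu, f must all have length k")
        for name, arr in (("lam", self.lam), ("mu", self.mu), ("q", self.q)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if np.any(self.f <= 0) or np.any(self.f > 1):
            raise ValueError("sampling fractions must lie in (0, 1]")

    @property
    def k(self) -> int:
        return self.lam.shape[0]

    # ---- flat named-vector serialization used by trace files -------------
    def param_names(self) -> list:
        k = self.k
        names = [f"lambda_{i}" for i in range(k)] + [f"mu_{i}" for i in range(k)]
        names += [f"q_{i}_{j}" for i in range(k) for j in range(k) if j != i]
        return names

    def to_named_vector(self) -> Dict[str, float]:
        k = self.k
        out = {f"lambda_{i}": float(self.lam[i]) for i in range(k)}
        out.update({f"mu_{i}": float(self.mu[i]) for i in range(k)})
        for i in range(k):
            for j in range(k):
                if j != i:
                    out[f"q_{i}_{j}"] = float(self.q[i, j])
        return out

    @classmethod
    def from_named_vector(cls, values: Dict[str, float], k: int,
                          f: Optional[np.ndarray] = None) -> "MusseParameters":
        lam = np.array([values[f"lambda_{i}"] for i in range(k)])
        mu = np.array([values[f"mu_{i}"] for i in range(k)])
        q = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if j != i:
                    q[i, j] = values[f"q_{i}_{j}"]
        return cls(lam, mu, q, f)


@dataclass
class LikelihoodOptions:
    """Root treatment and integration tolerances.

    ``root_mode``: 'obs' (weights proportional to the root D vector, the
    default), 'equal', or 'given' (supply ``root_weights``).  Conditioning on
    survival divides each root D_i by lambda_i (1 - E_i)^2 before weighting.
    """

    root_mode: str = "obs"
    root_weights: Optional[np.ndarray] = None
    condition_on_survival: bool = True
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if self.root_mode not in _ROOT_MODES:
            raise ValueError(f"unknown root mode {self.root_mode!r}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.root_mode == "given":
            w = np.asarray(self.root_weights, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("root weights must be non-negative, not all zero")
            self.root_weights = w


@dataclass
class OdeState:
    """State of the per-branch integration: E, D and log-compensation."""

    E: np.ndarray
    D: np.ndarray
    log_comp: float = 0.0

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.E.shape != self.D.shape:
            raise ValueError("E and D must have the same length")
        if np.any(self.E < 0) or np.any(self.E > 1):
            raise ValueError("E entries must lie in [0, 1]")
        if np.any(self.D < 0):
            raise ValueError("D entries must be non-negative")


def branch_integrate(s0: OdeState, t: float, p: MusseParameters,
                     opts: LikelihoodOptions = LikelihoodOptions()) -> OdeState:
    """Integrate (E, D) along a single branch of duration ``t``."""
    if t < 0:
        raise ValueError("branch duration must be non-negative")
    if s0.E.shape[0] != p.k:
        raise ValueError("OdeState dimension does not match parameter k")
    y = np.concatenate([s0.E, s0.D]).astype(float)
    qrow = p.q.sum(axis=1)
    scratch = np.empty((8, 2 * p.k))
    lc, status = core._integrate_branch(y, float(t), p.lam, p.mu, p.q, qrow,
                                        p.k, opts.rtol, opts.atol, scratch)
    _raise_on_status(status)
    E = np.minimum(np.maximum(y[: p.k], 0.0), 1.0)  # roundoff within _E_TOL only
    return OdeState(E=E, D=y[p.k:], log_comp=s0.log_comp + lc)


def _raise_on_status(status: int) -> None:
    if status == core.STEP_UNDERFLOW:
        raise SolverError("ODE step size underflow: tolerance could not be met")
    if status == core.E_OUT_OF_BOUNDS:
        raise SolverError("extinction probability left [0, 1] during integration")


def musse_loglik(tree: Phylogeny, states: TipStateMap, p: MusseParameters,
                 opts: LikelihoodOptions = LikelihoodOptions()) -> float:
    """Log-likelihood of tip states and tree under a k-state model.

    Tip initialization: D_i = f_i for the observed state (all states when the
    tip state is unknown), E_i = 1 - f_i.  Returns -inf when the data are
    impossible under ``p``.
    """
    if states.k != p.k:
        raise TreeError(f"state map has k={states.k} but parameters have k={p.k}")
    tipstate = states.encode(tree)
    rw = (np.asarray(opts.root_weights, dtype=float)
          if opts.root_mode == "given" else np.zeros(p.k))
    ll, status = core.musse_loglik_kernel(
        tree.left, tree.right, tree.blen, tipstate,
        p.lam, p.mu, p.q, p.f,
        opts.rtol, opts.atol,
        _ROOT_MODES[opts.root_mode], opts.condition_on_survival, rw,
    )
    _raise_on_status(status)
    if status == core.ZERO_LIKELIHOOD:
        return -np.inf
    return float(ll)


def parameter_count(k: int, hyper_scales: int = 3) -> int:
    """Free parameters of the full model: k speciation + k extinction +
    k(k-1) transition rates, plus the hyperprior scale parameters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if hyper_scales < 0:
        raise ValueError("hyper_scales must be >= 0")
    return 2 * k + k * (k - 1) + hyper_scales
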