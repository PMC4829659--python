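"""Guild-level transition network: weighted digraph of posterior median
transition rates, its eigenvector centrality, and a permutation null.

Centrality is *in*-centrality: a guild is central when transitions lead,
directly or indirectly, into it, so the leading eigenvector is taken of the
transposed weight matrix (x_j proportional to sum_i w_ij x_i), computed by
power iteration.  Reported centralities are normalized to max 1 (0 =
peripheral, 1 = most central).  The permutation null reassigns the multiset
of off-diagonal weights across the off-diagonal positions; the network
topology (complete digraph minus self-loops) is fixed and only values
shuffle.  The permutation comparison is made on 2-norm-normalized
centralities: max-normalization would pin every replica's most central node
at exactly 1 and erase the concentration signal the test is after, whereas
the 2-norm profile retains it (both normalizations order nodes identically).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mcmc import PosteriorTrace

__all__ = [
    "TransitionNetwork",
    "CentralityResult",
    "CentralityError",
    "build_network",
    "eigenvector_centrality",
    "centrality_permutation_test",
]


class CentralityError(RuntimeError):
    """Power iteration failed to converge (reducible/periodic structure)."""


@dataclass
class TransitionNetwork:
    """Node labels (guilds) and a non-negative weight matrix with zero
    diagonal; ``w[i, j]`` is the transition rate from guild i to guild j.
    ``display_cutoff`` affects rendering only, never any computation."""

    labels: Sequence[str]
    w: np.ndarray
    display_cutoff: float = 0.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).copy()
        k = len(self.labels)
        if self.w.shape != (k, k):
            raise ValueError("weight matrix must be square and match labels")
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite and non-negative")
        np.fill_diagonal(self.w, 0.0)

    @property
    def k(self) -> int:
        return len(self.labels)

    def display_matrix(self) -> np.ndarray:
        """Weights with entries below the rendering cutoff zeroed."""
        out = self.w.copy()
        out[out < self.display_cutoff] = 0.0
        return out

    def to_csv(self) -> str:
        lines = ["," + ",".join(self.labels)]
        for i, lb in enumerate(self.labels):
            lines.append(lb + "," + ",".join(f"{x:.10g}" for x in self.w[i]))
        return "\n".join(lines) + "\n"

    def to_dot(self, use_cutoff: bool = True) -> str:
        w = self.display_matrix() if use_cutoff else self.w
        lines = ["digraph transitions {"]
        for lb in self.labels:
            lines.append(f'  "{lb}";')
        for i in range(self.k):
            for j in range(self.k):
                if w[i, j] > 0:
                    lines.append(
                        f'  "{self.labels[i]}" -> "{self.labels[j]}"'
                        f' [label="{w[i, j]:.4g}", penwidth={1 + 4 * w[i, j] / w.max():.2f}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_network(trace: PosteriorTrace, guild_labels: Sequence[str],
                  display_cutoff: float = 0.001) -> TransitionNetwork:
    """Network with w[i, j] = posterior median of q_i_j from a trace."""
    k = len(guild_labels)
    if k != trace.k:
        raise ValueError(f"{k} labels but trace has k={trace.k}")
    w = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            col = f"q_{i}_{j}"
            if col not in trace.df.columns:
                raise ValueError(f"trace lacks column {col}")
            w[i, j] = float(np.median(trace.df[col].to_numpy()))
    return TransitionNetwork(list(guild_labels), w, display_cutoff)


def _power_iteration_batch(w_stack: np.ndarray, tol: float = 1e-12,
                           max_iter: int = 10_000):
    """In-centrality of a stack of weight matrices (B, k, k) by power
    iteration from a uniform start; returns 2-norm-normalized vectors.

    Oscillation (period-2 structure) is resolved by averaging the last two
    iterates; persistent non-convergence raises :class:`CentralityError`.
    """
    B, k, _ = w_stack.shape
    x = np.full((B, k), 1.0 / np.sqrt(k))
    prev = x.copy()
    for it in range(max_iter):
        xn = np.einsum("bi,bij->bj", x, w_stack)
        norms = np.linalg.norm(xn, axis=1, keepdims=True)
        dead = norms[:, 0] <= 0
        if np.any(dead):
            # no in-weight mass anywhere: undefined centrality
            raise CentralityError("weight matrix has no positive in-weights")
        xn /= norms
        if np.max(np.abs(xn - x)) < tol:
            return xn, it + 1
        if np.max(np.abs(xn - prev)) < tol:  # period-2 oscillation
            avg = 0.5 * (xn + x)
            n2 = np.linalg.norm(avg, axis=1, keepdims=True)
            if np.all(n2 > 0):
                return avg / n2, it + 1
        prev = x
        x = xn
    raise CentralityError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(max residual {np.max(np.abs(xn - x)):.3g})")


def eigenvector_centrality(net: TransitionNetwork, tol: float = 1e-12,
                           max_iter: int = 10_000) -> np.ndarray:
    """Per-node in-centrality, normalized so the maximum is exactly 1."""
    if not np.any(net.w > 0):
        raise ValueError("network needs at least one positive weight")
    x, _ = _power_iteration_batch(net.w[None, :, :], tol=tol, max_iter=max_iter)
    v = x[0]
    return v / v.max()


@dataclass
class CentralityResult:
    """Observed centralities (max = 1), one-sided permutation p-values and
    the provenance of the null (replica count, seed)."""

    labels: Sequence[str]
    centrality: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: Optional[int]

    def to_json(self) -> str:
        return json.dumps({
            "labels": list(self.labels),
            "centrality": self.centrality.tolist(),
            "p_values": self.p_values.tolist(),
            "n_perm": self.n_perm,
            "seed": self.seed,
        }, indent=2)


def centrality_permutation_test(net: TransitionNetwork, n_perm: int = 10_000,
                                seed: Optional[int] = None,
                                batch: int = 512) -> CentralityResult:
    """Permutation test of node centralities.

    Each replica redistributes the off-diagonal weights (sampled without
    replacement, i.e. a permutation of the multiset) over the off-diagonal
    positions; p_j = (1 + #{replicas with null centrality_j >= observed_j})
    / (1 + n_perm), computed on 2-norm-normalized centralities.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = net.k
    obs2, _ = _power_iteration_batch(net.w[None, :, :])
    obs2 = obs2[0]
    rng = np.random.default_rng(seed)
    off = ~np.eye(k, dtype=bool)
    vals = net.w[off]
    exceed = np.zeros(k)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        stack = np.zeros((b, k, k))
        perms = rng.permuted(np.tile(vals, (b, 1)), axis=1)
        stack[:, off] = perms
        null2, _ = _power_iteration_batch(stack)
        exceed += np.sum(null2 >= obs2[None, :] - 1e-12, axis=0)
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    cent = obs2 / obs2.max()
    return CentralityResult(list(net.labels), cent, p, n_perm, seed)
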