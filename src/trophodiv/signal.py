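"""Phylogenetic signal of a binary trait: the D statistic of character
dispersion.

The observed sister-clade difference sum d_obs (nodal values by recursive
child-mean averaging) is scaled against two simulated references on the same
tree: random shuffles of the tip values (D = 1 when states are
phylogenetically random) and threshold-discretized Brownian motion matched
to the observed prevalence (D = 0 under Brownian clumping).  D < 0 indicates
clustering stronger than Brownian; D >> 1, overdispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .trees import Phylogeny, TipStateMap, TreeError

__all__ = ["DStatResult", "d_statistic", "guild_signal"]


@dataclass
class DStatResult:
    """D plus its ingredients and the two one-sided significance tests:
    p_random (vs shuffled tips, departure toward clustering) and p_brownian
    (vs Brownian threshold simulations, departure toward randomness)."""

    D: float
    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    p_random: float
    p_brownian: float
    n_perm: int
    n_sim: int
    seed: Optional[int]

    def flags(self, alpha: float = 0.05) -> Dict[str, bool]:
        return {
            "different_from_random": self.p_random <= alpha,
            "different_from_brownian": self.p_brownian <= alpha,
        }

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d.update(self.flags())
        return json.dumps(d, indent=2)


def _sister_diff_sums(tree: Phylogeny, traits: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of |v(left) - v(right)|, where v(tip) is the
    trait value and v(node) is the mean of its children's values.

    ``traits``: (n_tips, m) matrix in the order of ``tree.tip_indices``;
    returns length-m sums (vectorized over columns).
    """
    n = tree.n_nodes
    m = traits.shape[1]
    V = np.zeros((n, m))
    tip_row = {int(t): r for r, t in enumerate(tree.tip_indices)}
    d = np.zeros(m)
    for nd in range(n):
        if tree.left[nd] < 0:
            V[nd] = traits[tip_row[nd]]
        else:
            a, b = V[tree.left[nd]], V[tree.right[nd]]
            V[nd] = 0.5 * (a + b)
            d += np.abs(a - b)
    return d


def _brownian_tips(tree: Phylogeny, m: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-rate Brownian tip values, (n_tips, m), preorder propagation."""
    n = tree.n_nodes
    X = np.zeros((n, m))
    par = tree.parent_array()
    for nd in range(n - 2, -1, -1):  # parents first
        X[nd] = X[par[nd]] + rng.standard_normal(m) * np.sqrt(tree.blen[nd])
    return X[tree.tip_indices]


def d_statistic(tree: Phylogeny, trait: Mapping[str, int],
                n_perm: int = 1_000, n_sim: int = 1_000,
                seed: Optional[int] = None) -> DStatResult:
    """Fritz-Purvis-style D of a binary trait on a binary tree.

    The Brownian reference thresholds each simulated continuous character at
    the quantile matching the observed prevalence.  p_random is the add-one
    corrected fraction of shuffles with d <= d_obs; p_brownian the fraction
    of Brownian replicates with d >= d_obs.
    """
    tips = tree.tip_labels
    try:
        obs = np.array([int(trait[t]) for t in
                        (tree.labels[i] for i in tree.tip_indices)])
    except KeyError as exc:
        raise TreeError(f"tip {exc} has no trait value") from None
    if not set(np.unique(obs)) <= {0, 1}:
        raise ValueError("trait must be binary (0/1)")
    n1 = int(obs.sum())
    ntip = len(obs)
    if n1 == 0 or n1 == ntip:
        raise ValueError("trait is constant across tips; D is undefined")
    rng = np.random.default_rng(seed)

    d_obs = float(_sister_diff_sums(tree, obs[:, None].astype(float))[0])

    shuffled = rng.permuted(np.tile(obs.astype(float), (n_perm, 1)), axis=1).T
    d_rand = _sister_diff_sums(tree, shuffled)

    X = _brownian_tips(tree, n_sim, rng)
    # prevalence matching: the minority class occupies the upper tail, which
    # makes the reference exactly invariant to swapping the state labels
    n_minor = min(n1, ntip - n1)
    order = np.argsort(X, axis=0)
    bm = np.zeros_like(X)
    rows = order[ntip - n_minor:, :]
    bm[rows, np.arange(n_sim)[None, :]] = 1.0
    d_brown = _sister_diff_sums(tree, bm)

    mr, mb = float(d_rand.mean()), float(d_brown.mean())
    if mr == mb:
        raise ValueError("degenerate references: shuffle and Brownian means equal")
    D = (d_obs - mb) / (mr - mb)
    p_random = (1.0 + float(np.sum(d_rand <= d_obs))) / (1.0 + n_perm)
    p_brownian = (1.0 + float(np.sum(d_brown >= d_obs))) / (1.0 + n_sim)
    return DStatResult(float(D), d_obs, mr, mb, p_random, p_brownian,
                       n_perm, n_sim, seed)


def guild_signal(trees: Sequence[Phylogeny], assignment: Mapping[str, str],
                 guild: str, n_perm: int = 1_000, n_sim: int = 1_000,
                 seed: Optional[int] = None) -> Dict:
    """One-vs-rest D of a guild averaged over a set of trees.

    Per-tree significance flags are reported together with their majority
    verdicts.
    """
    rng = np.random.default_rng(seed)
    results = []
    for tree in trees:
        trait = {sp: int(assignment[sp] == guild) for sp in tree.tip_labels}
        results.append(d_statistic(tree, trait, n_perm, n_sim,
                                   seed=int(rng.integers(2 ** 31))))
    flags = [r.flags() for r in results]
    return {
        "guild": guild,
        "mean_D": float(np.mean([r.D for r in results])),
        "per_tree_D": [r.D for r in results],
        "per_tree_flags": flags,
        "majority_different_from_random":
            sum(f["different_from_random"] for f in flags) > len(flags) / 2,
        "majority_different_from_brownian":
            sum(f["different_from_brownian"] for f in flags) > len(flags) / 2,
    }
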