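"""Forward simulation under state-dependent diversification.

Gillespie event simulation of trees whose per-lineage speciation, extinction
and state-transition rates depend on a discrete state; neutral (Mk)
character simulation on fixed trees; and the two simulation-based checks the
pipeline supports: a posterior-predictive adequacy test on tip-state
proportions, and a neutral-character false-positive test that refits the
full model to characters simulated with no effect on diversification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .likelihood import LikelihoodOptions, MusseParameters
from .mcmc import McmcConfig, PosteriorTrace, rate_differences, run_mcmc
from .trees import Phylogeny, TipStateMap, TreeError

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "TotalExtinctionError",
    "AdequacyResult",
    "simulate_musse_tree",
    "simulate_mk_character",
    "adequacy_test",
    "neutral_association_test",
]


class SimulationError(RuntimeError):
    pass


class TotalExtinctionError(SimulationError):
    """Every lineage died before the stop rule was reached."""


@dataclass
class SimulationConfig:
    """Stop on a target number of extant tips OR at a target time (exactly
    one).  The process starts from a single stem lineage at time 0; the
    returned tree is rooted at the first bifurcation with surviving
    descendants on both sides, extinct lineages pruned."""

    params: MusseParameters
    n_tips: Optional[int] = None
    max_time: Optional[float] = None
    root_state: Optional[int] = None  # None: stationary draw from q
    seed: Optional[int] = None
    max_events: int = 1_000_000
    return_complete: bool = False

    def __post_init__(self):
        if (self.n_tips is None) == (self.max_time is None):
            raise ValueError("specify exactly one stop rule: n_tips or max_time")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.max_events <= 0:
            raise ValueError("max_events must be positive")


def _stationary_state(q: np.ndarray, rng: np.random.Generator) -> int:
    k = q.shape[0]
    gen = q - np.diag(q.sum(axis=1))
    # left null vector of the generator
    vals, vecs = np.linalg.eig(gen.T)
    i = int(np.argmin(np.abs(vals)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    if pi.sum() <= 0:
        pi = np.ones(k)
    pi = pi / pi.sum()
    return int(rng.choice(k, p=pi))


def simulate_musse_tree(cfg: SimulationConfig):
    """Simulate one tree; returns (Phylogeny, TipStateMap) — plus the
    complete tree (extinct tips included) when ``return_complete``.

    Stop-on-taxa samples the tree at the moment the (n+1)-th extant lineage
    would appear (the first speciation drawn while n lineages are alive),
    avoiding the bias of stopping exactly at the n-th birth.
    """
    p = cfg.params
    k = p.k
    rng = np.random.default_rng(cfg.seed)
    root_state = (cfg.root_state if cfg.root_state is not None
                  else _stationary_state(p.q, rng))
    if not (0 <= root_state < k):
        raise ValueError("root state outside 0..k-1")
    tot_rate = p.lam + p.mu + p.q.sum(axis=1)

    # per-lineage records
    parent = [-1]
    t_start = [0.0]
    t_end = [math.nan]
    state = [int(root_state)]
    children: List[Optional[Tuple[int, int]]] = [None]
    alive_flag = [True]
    active = [0]

    t = 0.0
    stop_time = cfg.max_time
    n_events = 0
    while True:
        rates = np.array([tot_rate[state[i]] for i in active])
        total = rates.sum()
        if total <= 0:
            if stop_time is None:
                raise SimulationError(
                    "all rates zero before reaching the target tip count")
            t = stop_time
            break
        dt = rng.exponential(1.0 / total)
        if stop_time is not None and t + dt > stop_time:
            t = stop_time
            break
        t += dt
        n_events += 1
        if n_events > cfg.max_events:
            raise SimulationError(f"event cap {cfg.max_events} exceeded")
        cum = np.cumsum(rates)
        lin = active[int(np.searchsorted(cum, rng.uniform(0.0, total)))]
        s = state[lin]
        u = rng.uniform(0.0, tot_rate[s])
        if u < p.lam[s]:
            if cfg.n_tips is not None and len(active) == cfg.n_tips:
                break  # the (n+1)-th birth would occur now: sample here
            t_end[lin] = t
            alive_flag[lin] = False
            ids = []
            for _ in range(2):
                parent.append(lin)
                t_start.append(t)
                t_end.append(math.nan)
                state.append(s)
                children.append(None)
                alive_flag.append(True)
                ids.append(len(parent) - 1)
            children[lin] = (ids[0], ids[1])
            active.remove(lin)
            active.extend(ids)
        elif u < p.lam[s] + p.mu[s]:
            t_end[lin] = t
            alive_flag[lin] = False
            active.remove(lin)
            if not active:
                raise TotalExtinctionError(
                    f"clade died out at t={t:.4g} after {n_events} events")
        else:
            u2 = u - p.lam[s] - p.mu[s]
            cq = np.cumsum([p.q[s, j] for j in range(k)])
            state[lin] = int(np.searchsorted(cq, u2, side="right"))

    if len(active) < 2:
        raise TotalExtinctionError("fewer than 2 surviving lineages at stop time")
    for lin in active:
        t_end[lin] = t

    # assemble the complete genealogy as a postorder-numbered Phylogeny
    n_alive = 0
    n_dead = 0
    labels_full = {}
    for lin in range(len(parent)):
        if children[lin] is None:
            if alive_flag[lin]:
                n_alive += 1
                labels_full[lin] = f"t{n_alive}"
            else:
                n_dead += 1
                labels_full[lin] = f"x{n_dead}"
    left, right, blen, labels, states_out = [], [], [], [], []
    index = {}
    stack = [(0, False)]
    while stack:
        lin, expanded = stack.pop()
        if children[lin] is not None and not expanded:
            stack.append((lin, True))
            stack.append((children[lin][1], False))
            stack.append((children[lin][0], False))
            continue
        if children[lin] is None:
            left.append(-1)
            right.append(-1)
            labels.append(labels_full[lin])
        else:
            left.append(index[children[lin][0]])
            right.append(index[children[lin][1]])
            labels.append("")
        blen.append(t_end[lin] - t_start[lin])
        index[lin] = len(blen) - 1
    complete = Phylogeny(left, right, blen, labels)
    tip_states_all = {labels_full[lin]: state[lin]
                      for lin in range(len(parent)) if children[lin] is None}

    alive_labels = [labels_full[lin] for lin in active]
    pruned = complete.prune_to(alive_labels)
    smap = TipStateMap({lb: tip_states_all[lb] for lb in alive_labels}, k=k)
    if cfg.return_complete:
        return pruned, smap, complete
    return pruned, smap


def simulate_mk_character(tree: Phylogeny, q: np.ndarray,
                          root_state: Optional[int] = None,
                          seed: Optional[int] = None) -> TipStateMap:
    """Evolve a neutral discrete character along a fixed tree.

    The state follows a continuous-time Markov chain with off-diagonal rates
    ``q[i, j]`` along every branch; tip states are returned.
    """
    q = np.asarray(q, dtype=float).copy()
    np.fill_diagonal(q, 0.0)
    if np.any(q < 0):
        raise ValueError("transition rates must be non-negative")
    k = q.shape[0]
    rng = np.random.default_rng(seed)
    if root_state is None:
        root_state = _stationary_state(q, rng)
    out_rate = q.sum(axis=1)
    node_state = np.empty(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = root_state
    par = tree.parent_array()
    result = {}
    for nd in range(tree.n_nodes - 2, -1, -1):  # preorder (parents first)
        s = int(node_state[par[nd]])
        remaining = float(tree.blen[nd])
        while out_rate[s] > 0:
            w = rng.exponential(1.0 / out_rate[s])
            if w >= remaining:
                break
            remaining -= w
            cq = np.cumsum(q[s])
            s = int(np.searchsorted(cq, rng.uniform(0.0, out_rate[s]), side="right"))
        node_state[nd] = s
        if tree.left[nd] < 0:
            result[tree.labels[nd]] = s
    return TipStateMap(result, k=k)


@dataclass
class AdequacyResult:
    """Posterior-predictive check on tip-state proportions.

    ``proportions``: n_trees x k matrix of simulated tip-state proportions;
    ``envelope``: 2.5-97.5 percentile band per state; ``inside``: whether
    each empirical proportion falls inside its band.
    """

    proportions: np.ndarray
    empirical: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    inside: np.ndarray
    n_failed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "empirical": self.empirical.tolist(),
            "envelope_low": self.envelope_low.tolist(),
            "envelope_high": self.envelope_high.tolist(),
            "inside": self.inside.tolist(),
            "n_trees": int(self.proportions.shape[0]),
            "n_failed": self.n_failed,
        }, indent=2)


def tip_state_proportions(smap: TipStateMap) -> np.ndarray:
    counts = np.zeros(smap.k)
    for v in smap.values():
        if v is not None:
            counts[v] += 1
    return counts / counts.sum()


def adequacy_test(p: MusseParameters, n_trees: int,
                  empirical_proportions: Sequence[float],
                  n_tips: Optional[int] = None,
                  max_time: Optional[float] = None,
                  root_state: Optional[int] = None,
                  seed: Optional[int] = None,
                  max_tries_factor: int = 10) -> AdequacyResult:
    """Simulate ``n_trees`` trees under ``p`` and flag whether each
    empirical tip-state proportion lies inside the simulated 95% envelope."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    emp = np.asarray(empirical_proportions, dtype=float)
    if emp.shape != (p.k,):
        raise ValueError("empirical proportions must have length k")
    rng = np.random.default_rng(seed)
    props = []
    failed = 0
    tries = 0
    while len(props) < n_trees:
        tries += 1
        if tries > max_tries_factor * n_trees:
            raise TotalExtinctionError(
                f"only {len(props)}/{n_trees} simulations survived")
        cfg = SimulationConfig(p, n_tips=n_tips, max_time=max_time,
                               root_state=root_state,
                               seed=int(rng.integers(2 ** 31)))
        try:
            _, smap = simulate_musse_tree(cfg)
        except TotalExtinctionError:
            failed += 1
            continue
        props.append(tip_state_proportions(smap))
    mat = np.vstack(props)
    lo = np.percentile(mat, 2.5, axis=0)
    hi = np.percentile(mat, 97.5, axis=0)
    inside = (emp >= lo) & (emp <= hi)
    return AdequacyResult(mat, emp, lo, hi, inside, n_failed=failed)


def neutral_association_test(trees: Sequence[Phylogeny], q_hat: np.ndarray,
                             mcmc_cfg: McmcConfig,
                             seed: Optional[int] = None,
                             opts: LikelihoodOptions = LikelihoodOptions(),
                             level: float = 0.95,
                             constrain_equal_rates: bool = False):
    """Fit the full model to characters simulated with NO effect on
    diversification (rates ``q_hat``), and report per tree whether any
    between-state speciation or extinction difference is flagged
    significant.  Returns (per-tree records, false-positive fraction).
    """
    if not trees:
        raise ValueError("empty tree list")
    rng = np.random.default_rng(seed)
    k = np.asarray(q_hat).shape[0]
    records = []
    for tree in trees:
        smap = simulate_mk_character(tree, q_hat, seed=int(rng.integers(2 ** 31)))
        if len(set(v for v in smap.values())) < 2:
            records.append({"tree": tree.tag, "skipped": True, "flagged": False})
            continue
        from dataclasses import replace as _replace
        cfg = _replace(mcmc_cfg, seed=int(rng.integers(2 ** 31)))
        trace = run_mcmc(tree, smap, cfg, opts,
                         constrain_equal_rates=constrain_equal_rates).trim()
        flagged = False
        pairs = []
        for focal in range(k):
            comp = rate_differences(trace, focal, levels=(level,))
            for rate in ("speciation", "extinction"):
                for s, lv in comp.significant[rate].items():
                    if lv[level]:
                        flagged = True
                        pairs.append((rate, focal, s))
        records.append({"tree": tree.tag, "skipped": False,
                        "flagged": flagged, "pairs": pairs})
    tested = [r for r in records if not r["skipped"]]
    frac = (sum(r["flagged"] for r in tested) / len(tested)) if tested else float("nan")
    return records, frac
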