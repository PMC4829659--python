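"""Bayesian MCMC over state-dependent diversification parameters.

Each rate family (speciation, extinction, transition) gets a half-Cauchy
prior with location 0 and a family-specific scale that is itself estimated
(hyperprior), keeping rates small-but-positive without pinning them to zero.
Sampling is univariate slice sampling on the natural (positive) scale,
cycling over all rates and the three hyper-scales; traces from independently
fitted trees are combined into a single posterior per parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _musse_core as core
from .likelihood import (LikelihoodOptions, MusseParameters, SolverError,
                         _ROOT_MODES, musse_loglik)
from .trees import Phylogeny, TipStateMap

__all__ = [
    "HyperpriorState",
    "McmcConfig",
    "PosteriorTrace",
    "RateComparison",
    "half_cauchy_logpdf",
    "log_prior",
    "run_mcmc",
    "combine_traces",
    "net_diversification",
    "hpd_interval",
    "rate_differences",
]

_SCHEMA = "trophodiv-trace v1"
HPD_LEVELS = (0.95, 0.90, 0.80)


@dataclass
class HyperpriorState:
    """Scales of the three half-Cauchy hyperpriors (location fixed at 0),
    one per rate family."""

    s_lambda: float
    s_mu: float
    s_q: float

    def __post_init__(self):
        if min(self.s_lambda, self.s_mu, self.s_q) <= 0:
            raise ValueError("hyperprior scales must be positive")


@dataclass
class McmcConfig:
    """Chain settings.  A step is one full update cycle over all parameters;
    every ``thin``-th cycle is retained, so a chain keeps
    ``floor(steps / thin)`` samples; ``burn_in`` is the fraction of retained
    samples discarded when traces are analysed or combined."""

    steps: int = 1_500_000
    thin: int = 1_000
    burn_in: float = 0.1
    seed: Optional[int] = None
    hyper_bounds: Tuple[float, float] = (1e-4, 1e2)
    hyper_prior: str = "uniform"  # or "log-uniform"
    rate_max: float = 1e3
    slice_max_step_out: int = 20
    tune_widths: bool = True
    prior_only: bool = False

    def __post_init__(self):
        if not (self.steps >= self.thin >= 1):
            raise ValueError("need steps >= thin >= 1")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in must lie in [0, 1)")
        a, b = self.hyper_bounds
        if not (0 < a < b):
            raise ValueError("hyper_bounds must satisfy 0 < low < high")
        if self.hyper_prior not in ("uniform", "log-uniform"):
            raise ValueError("hyper_prior must be 'uniform' or 'log-uniform'")

    @property
    def n_retained(self) -> int:
        return self.steps // self.thin


def half_cauchy_logpdf(x: float, scale: float) -> float:
    """log density of |Cauchy(0, scale)| at x > 0; -inf for x <= 0."""
    if x <= 0:
        return -math.inf
    z = x / scale
    return math.log(2.0 / (math.pi * scale)) - math.log1p(z * z)


def log_prior(p: MusseParameters, h: HyperpriorState,
              hyper_bounds: Tuple[float, float] = (1e-4, 1e2),
              hyper_prior: str = "uniform") -> float:
    """Joint log prior: rates under family half-Cauchys, hyper-scales
    uniform (default) or log-uniform on ``hyper_bounds``.

    The uniform default avoids the strong extinction-rate shrinkage a
    log-uniform scale prior induces (its marginal behaves like 1/rate inside
    the band), which pushes weakly-informed rates toward zero.  -inf signals
    rejection.
    """
    a, b = hyper_bounds
    lp = 0.0
    for s in (h.s_lambda, h.s_mu, h.s_q):
        if not (a <= s <= b):
            return -math.inf
        if hyper_prior == "log-uniform":
            lp += -math.log(s) - math.log(math.log(b / a))
        else:
            lp += -math.log(b - a)
    for x in p.lam:
        lp += half_cauchy_logpdf(float(x), h.s_lambda)
    for x in p.mu:
        lp += half_cauchy_logpdf(float(x), h.s_mu)
    k = p.k
    for i in range(k):
        for j in range(k):
            if j != i:
                lp += half_cauchy_logpdf(float(p.q[i, j]), h.s_q)
    return lp


class PosteriorTrace:
    """MCMC samples of all parameters, possibly concatenated across trees.

    Columns: ``iter, tree_tag, loglik, logpost, lambda_*, mu_*, q_i_j,
    s_lambda, s_mu, s_q``.
    """

    def __init__(self, df: pd.DataFrame, k: int, burn_in: float = 0.0):
        required = {"iter", "tree_tag", "loglik", "logpost", "s_lambda", "s_mu", "s_q"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace missing columns: {sorted(missing)}")
        if df.drop(columns=["tree_tag"]).isna().any().any():
            raise ValueError("trace contains missing values")
        self.df = df.reset_index(drop=True)
        self.k = int(k)
        self.burn_in = float(burn_in)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def param_names(self) -> List[str]:
        fixed = {"iter", "tree_tag", "loglik", "logpost"}
        return [c for c in self.df.columns if c not in fixed]

    def trim(self) -> "PosteriorTrace":
        """Drop the per-trace burn-in fraction (by tree tag, preserving
        source-tree structure)."""
        if self.burn_in == 0:
            return self
        parts = []
        for _, g in self.df.groupby("tree_tag", sort=False, dropna=False):
            parts.append(g.iloc[int(math.floor(self.burn_in * len(g))):])
        return PosteriorTrace(pd.concat(parts, ignore_index=True), self.k, 0.0)

    def ess(self) -> Dict[str, float]:
        """Effective sample sizes of the rate parameters (post burn-in)."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az
        sub = self.trim().df
        out = {}
        for c in self.param_names:
            out[c] = float(az.ess(np.asarray(sub[c], dtype=float)))
        return out

    # ------------------------------------------------------------------ I/O
    def to_csv(self) -> str:
        buf = StringIO()
        buf.write(f"# {_SCHEMA} k={self.k} burn_in={self.burn_in}\n")
        self.df.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "PosteriorTrace":
        lines = text.splitlines()
        if not lines or not lines[0].startswith(f"# {_SCHEMA}"):
            raise ValueError("not a recognized trace file (schema header missing)")
        header = dict(tok.split("=") for tok in lines[0].split()[3:])
        df = pd.read_csv(StringIO("\n".join(lines[1:])))
        df["tree_tag"] = df["tree_tag"].fillna("").astype(str)
        return cls(df, k=int(header["k"]), burn_in=float(header.get("burn_in", 0.0)))


# ------------------------------------------------------------------ sampler

def _slice_update(x0: float, f0: float, logf: Callable[[float], float],
                  w: float, rng: np.random.Generator,
                  lower: float, upper: float, max_out: int) -> Tuple[float, float]:
    """One univariate slice-sampling update (stepping out + shrinkage).

    ``f0`` must equal ``logf(x0)``; returns (x1, logf(x1))."""
    y = f0 - rng.exponential(1.0)
    u = rng.uniform(0.0, w)
    L = x0 - u
    R = L + w
    j = int(rng.integers(0, max_out + 1))
    m = max_out - j
    while j > 0 and L > lower and logf(L) > y:
        L -= w
        j -= 1
    while m > 0 and R < upper and logf(R) > y:
        R += w
        m -= 1
    L = max(L, lower)
    R = min(R, upper)
    for _ in range(200):
        x1 = rng.uniform(L, R)
        f1 = logf(x1)
        if f1 > y:
            return x1, f1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0, f0  # degenerate slice; keep current point


def run_mcmc(tree: Phylogeny, states: TipStateMap, cfg: McmcConfig,
             opts: LikelihoodOptions = LikelihoodOptions(),
             tree_tag: Optional[str] = None,
             init: Optional[MusseParameters] = None,
             constrain_equal_rates: bool = False) -> PosteriorTrace:
    """Sample the posterior of all rates and hyper-scales for one tree.

    ``constrain_equal_rates`` ties speciation rates to a single shared value
    and extinction rates likewise (transition rates stay free) — the
    constrained model used as a null in the neutral-character check.
    """
    k = states.k
    rng = np.random.default_rng(cfg.seed)
    height = tree.tree_height()
    lam0 = max(math.log(max(tree.n_tips, 2)) / max(height, 1e-6), 1e-3)
    mu0 = lam0 / 5.0
    q0 = max(0.1 * lam0, 1e-4)

    lam = np.full(k, lam0)
    mu = np.full(k, mu0)
    q = np.full((k, k), q0)
    np.fill_diagonal(q, 0.0)
    if init is not None:
        lam, mu, q = init.lam.copy(), init.mu.copy(), init.q.copy()
    hb = cfg.hyper_bounds
    hyper = np.clip(np.array([lam0, mu0, q0]), hb[0], hb[1])

    # parameter bookkeeping: (family, accessor) per sampled scalar
    qpos = [(i, j) for i in range(k) for j in range(k) if j != i]
    if constrain_equal_rates:
        rate_params = [("lam_all", None), ("mu_all", None)] + [("q", ij) for ij in qpos]
    else:
        rate_params = ([("lam", i) for i in range(k)] + [("mu", i) for i in range(k)]
                       + [("q", ij) for ij in qpos])

    def current_params() -> MusseParameters:
        return MusseParameters(lam.copy(), mu.copy(), q.copy())

    # fast likelihood path: tip states encoded once, kernel called directly
    tipstate = states.encode(tree)
    fvec = np.ones(k)
    rw = (np.asarray(opts.root_weights, dtype=float)
          if opts.root_mode == "given" else np.zeros(k))
    rmode = _ROOT_MODES[opts.root_mode]

    def loglik() -> float:
        ll, status = core.musse_loglik_kernel(
            tree.left, tree.right, tree.blen, tipstate, lam, mu, q, fvec,
            opts.rtol, opts.atol, rmode, opts.condition_on_survival, rw)
        if status in (core.STEP_UNDERFLOW, core.E_OUT_OF_BOUNDS):
            raise SolverError("ODE integration failed")
        if status == core.ZERO_LIKELIHOOD:
            return -math.inf
        return float(ll)

    if cfg.prior_only:
        def loglik() -> float:  # noqa: F811 - deliberate override
            return 0.0

    def logprior() -> float:
        return log_prior(current_params(), HyperpriorState(*hyper),
                         cfg.hyper_bounds, cfg.hyper_prior)

    try:
        cur_ll = loglik()
    except Exception as exc:
        raise RuntimeError(
            f"likelihood failed at initial parameters "
            f"{current_params().to_named_vector()}: {exc}") from exc
    cur_lp = logprior()
    if not np.isfinite(cur_ll + cur_lp):
        raise RuntimeError("initial parameter vector has zero posterior density")

    widths = {"lam": lam0, "lam_all": lam0, "mu": mu0, "mu_all": mu0,
              "q": 2 * q0, "hyper": 1.0}
    a, b = cfg.hyper_bounds

    def set_rate(name, idx, value):
        if name == "lam":
            lam[idx] = value
        elif name == "mu":
            mu[idx] = value
        elif name == "lam_all":
            lam[:] = value
        elif name == "mu_all":
            mu[:] = value
        else:
            q[idx] = value

    def get_rate(name, idx):
        if name == "lam" or name == "lam_all":
            return float(lam[0 if name == "lam_all" else idx])
        if name == "mu" or name == "mu_all":
            return float(mu[0 if name == "mu_all" else idx])
        return float(q[idx])

    n_ret = cfg.n_retained
    names = ([f"lambda_{i}" for i in range(k)] + [f"mu_{i}" for i in range(k)]
             + [f"q_{i}_{j}" for i, j in qpos] + ["s_lambda", "s_mu", "s_q"])
    records = np.empty((n_ret, len(names) + 3))  # + iter, loglik, logpost
    rec = 0
    tune_until = max(1, int(cfg.burn_in * cfg.steps))
    moves: Dict[str, List[float]] = {fam: [] for fam in ("lam", "mu", "q")}

    for step in range(1, cfg.steps + 1):
        for fam, idx in rate_params:
            x0 = get_rate(fam, idx)
            famkey = fam.replace("_all", "")

            def logf(x):
                if x <= 0 or x > cfg.rate_max:
                    return -math.inf
                set_rate(fam, idx, x)
                try:
                    ll = loglik()
                except SolverError as exc:
                    raise RuntimeError(
                        f"likelihood failed at {fam}{idx}={x}: "
                        f"{current_params().to_named_vector()}") from exc
                return ll + logprior()

            f0 = cur_ll + cur_lp
            x1, f1 = _slice_update(x0, f0, logf, widths[fam], rng,
                                   0.0, cfg.rate_max, cfg.slice_max_step_out)
            set_rate(fam, idx, x1)
            cur_lp = logprior()
            cur_ll = f1 - cur_lp
            if cfg.tune_widths and step <= tune_until and x1 != x0:
                moves[famkey].append(abs(x1 - x0))

        # hyper-scales: conditional involves the prior only
        for hi in (0, 1, 2):

            def logf_h(s):
                if not (a <= s <= b):
                    return -math.inf
                old = hyper[hi]
                hyper[hi] = s
                lp = logprior()
                hyper[hi] = old
                return lp

            s0 = float(hyper[hi])
            f0 = logf_h(s0)
            s1, _ = _slice_update(s0, f0, logf_h, widths["hyper"], rng,
                                  a, b, cfg.slice_max_step_out)
            hyper[hi] = s1
        cur_lp = logprior()

        if cfg.tune_widths and step == tune_until:
            for famkey in moves:
                if moves[famkey]:
                    w = 2.5 * float(np.mean(moves[famkey]))
                    widths[famkey] = max(w, 1e-6)
                    widths[famkey + "_all"] = widths[famkey]

        if step % cfg.thin == 0:
            row = ([float(v) for v in lam] + [float(v) for v in mu]
                   + [float(q[ij]) for ij in qpos] + [float(v) for v in hyper])
            records[rec, 0] = step
            records[rec, 1] = cur_ll
            records[rec, 2] = cur_ll + cur_lp
            records[rec, 3:] = row
            rec += 1

    df = pd.DataFrame(records[:rec, 3:], columns=names)
    df.insert(0, "logpost", records[:rec, 2])
    df.insert(0, "loglik", records[:rec, 1])
    df.insert(0, "tree_tag", tree_tag if tree_tag is not None else (tree.tag or ""))
    df.insert(0, "iter", records[:rec, 0].astype(int))
    return PosteriorTrace(df, k=k, burn_in=cfg.burn_in)


# ------------------------------------------------------------- trace algebra

def combine_traces(traces: Sequence[PosteriorTrace]) -> PosteriorTrace:
    """Concatenate per-tree posteriors after per-trace burn-in removal."""
    if not traces:
        raise ValueError("no traces to combine")
    ks = {t.k for t in traces}
    if len(ks) != 1:
        raise ValueError(f"refusing to combine traces with different k: {sorted(ks)}")
    names = traces[0].param_names
    for t in traces[1:]:
        if t.param_names != names:
            raise ValueError("parameter-name mismatch between traces")
    parts = [t.trim().df for t in traces]
    return PosteriorTrace(pd.concat(parts, ignore_index=True), traces[0].k, 0.0)


def net_diversification(trace: PosteriorTrace) -> pd.DataFrame:
    """Per-sample net diversification r_i = lambda_i - mu_i, per state."""
    out = {}
    for i in range(trace.k):
        li, mi = f"lambda_{i}", f"mu_{i}"
        if li not in trace.df.columns or mi not in trace.df.columns:
            raise ValueError(f"trace lacks columns {li}/{mi}")
        out[f"r_{i}"] = trace.df[li].to_numpy() - trace.df[mi].to_numpy()
    return pd.DataFrame(out)


def hpd_interval(samples: Sequence[float], mass: float) -> Tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted
    samples (single interval by construction)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    if not (0 < mass <= 1):
        raise ValueError("mass must lie in (0, 1]")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class RateComparison:
    """Posterior rate differences of every guild against a focal guild
    (guild rate minus focal rate), with HPD bounds at 95/90/80% and a
    significance flag per level (0 outside the interval)."""

    focal: int
    differences: Dict[str, Dict[int, np.ndarray]]
    hpd: Dict[str, Dict[int, Dict[float, Tuple[float, float]]]]
    significant: Dict[str, Dict[int, Dict[float, bool]]]

    def to_json(self) -> str:
        payload = {"focal_state": self.focal, "rates": {}}
        for rate, per_state in self.hpd.items():
            payload["rates"][rate] = {
                str(s): {
                    f"{int(level*100)}": {
                        "interval": list(iv),
                        "significant": bool(self.significant[rate][s][level]),
                    }
                    for level, iv in levels.items()
                }
                for s, levels in per_state.items()
            }
        return json.dumps(payload, indent=2)


def rate_differences(trace: PosteriorTrace, focal: int,
                     levels: Sequence[float] = HPD_LEVELS) -> RateComparison:
    """Per-sample differences (state rate - focal rate) for speciation,
    extinction and net diversification; significant at a level iff 0 lies
    outside that HPD interval."""
    if not (0 <= focal < trace.k):
        raise ValueError(f"focal state {focal} not in 0..{trace.k - 1}")
    r = net_diversification(trace)
    source = {
        "speciation": {i: trace.df[f"lambda_{i}"].to_numpy() for i in range(trace.k)},
        "extinction": {i: trace.df[f"mu_{i}"].to_numpy() for i in range(trace.k)},
        "net_diversification": {i: r[f"r_{i}"].to_numpy() for i in range(trace.k)},
    }
    diffs: Dict[str, Dict[int, np.ndarray]] = {}
    hpds: Dict[str, Dict[int, Dict[float, Tuple[float, float]]]] = {}
    sig: Dict[str, Dict[int, Dict[float, bool]]] = {}
    for rate, per_state in source.items():
        diffs[rate], hpds[rate], sig[rate] = {}, {}, {}
        for s in range(trace.k):
            if s == focal:
                continue
            d = per_state[s] - per_state[focal]
            diffs[rate][s] = d
            hpds[rate][s] = {}
            sig[rate][s] = {}
            for level in levels:
                lo, hi = hpd_interval(d, level)
                hpds[rate][s][level] = (lo, hi)
                sig[rate][s][level] = not (lo <= 0.0 <= hi)
    return RateComparison(focal, diffs, hpds, sig)
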