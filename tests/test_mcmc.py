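import math

import numpy as np
import pandas as pd
import pytest

import trophodiv as td
from trophodiv.mcmc import HyperpriorState, half_cauchy_logpdf, log_prior

from conftest import random_yule_tree, simulate_surviving


class TestPrior:
    def test_half_cauchy_at_zero(self):
        for s in (0.5, 1.0, 2.0):
            assert math.exp(half_cauchy_logpdf(1e-300, s)) == \
                pytest.approx(2 / (math.pi * s), rel=1e-6)

    def test_doubling_scale_halves_density_at_zero(self):
        d1 = half_cauchy_logpdf(1e-300, 1.0)
        d2 = half_cauchy_logpdf(1e-300, 2.0)
        assert d1 - d2 == pytest.approx(math.log(2.0))

    def test_negative_rate_rejected(self):
        p = td.MusseParameters([0.3], [0.1], [[0.0]])
        p.mu[0] = -0.1  # bypass constructor validation deliberately
        assert log_prior(p, HyperpriorState(1, 1, 1)) == -math.inf

    def test_prior_finite_for_valid(self):
        p = td.MusseParameters([0.3, 0.1], [0.05, 0.02],
                               [[0, 0.01], [0.02, 0]])
        assert np.isfinite(log_prior(p, HyperpriorState(0.5, 0.5, 0.5)))


class TestRunMcmc:
    @pytest.fixture(scope="class")
    def fit_inputs(self):
        p = td.MusseParameters([0.4, 0.3], [0.05, 0.05], [[0, 0.05], [0.05, 0]])
        tree, states = simulate_surviving(p, seed=42, n_tips=60, root_state=0)
        return tree, states

    def test_deterministic_under_seed(self, fit_inputs):
        tree, states = fit_inputs
        cfg = td.McmcConfig(steps=120, thin=4, seed=99)
        t1 = td.run_mcmc(tree, states, cfg)
        t2 = td.run_mcmc(tree, states, cfg)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_retained_sample_accounting(self, fit_inputs):
        tree, states = fit_inputs
        cfg = td.McmcConfig(steps=100, thin=10, seed=1)
        trace = td.run_mcmc(tree, states, cfg)
        assert len(trace) == 10
        assert cfg.n_retained == 10
        assert trace.ess()  # computable

    def test_constrained_run_ties_rates(self, fit_inputs):
        tree, states = fit_inputs
        cfg = td.McmcConfig(steps=60, thin=3, seed=5)
        trace = td.run_mcmc(tree, states, cfg, constrain_equal_rates=True)
        assert np.allclose(trace.df["lambda_0"], trace.df["lambda_1"])
        assert np.allclose(trace.df["mu_0"], trace.df["mu_1"])

    def test_prior_only_chain_matches_half_cauchy(self):
        """With the likelihood silenced and the hyper-scale pinned at 1 the
        marginal of each rate is half-Cauchy(0, 1)."""
        tree = random_yule_tree(6, seed=2)
        states = td.TipStateMap({t: 0 for t in tree.tip_labels}, k=1)
        cfg = td.McmcConfig(steps=4000, thin=2, burn_in=0.1, seed=17,
                            prior_only=True, hyper_bounds=(0.999, 1.001),
                            rate_max=1e5, tune_widths=False)
        trace = td.run_mcmc(tree, states, cfg).trim()
        lam = np.asarray(trace.df["lambda_0"])
        # quantiles of |Cauchy(0,1)|: tan(pi q / 2)
        for q in (0.25, 0.5, 0.75):
            expected = math.tan(math.pi * q / 2)
            assert np.quantile(lam, q) == pytest.approx(expected, rel=0.25)

    def test_trace_csv_round_trip(self, fit_inputs):
        tree, states = fit_inputs
        cfg = td.McmcConfig(steps=40, thin=4, seed=3)
        trace = td.run_mcmc(tree, states, cfg)
        back = td.PosteriorTrace.from_csv(trace.to_csv())
        assert back.k == trace.k
        pd.testing.assert_frame_equal(back.df, trace.df, check_exact=False)


class TestTraceAlgebra:
    def _toy_trace(self, values, tag="t"):
        n = len(values)
        df = pd.DataFrame({
            "iter": np.arange(n), "tree_tag": tag,
            "loglik": 0.0, "logpost": 0.0,
            "lambda_0": values, "mu_0": np.asarray(values) / 2,
            "s_lambda": 1.0, "s_mu": 1.0, "s_q": 1.0,
        })
        return td.PosteriorTrace(df, k=1, burn_in=0.1)

    def test_combine_accounting(self):
        t = self._toy_trace(np.linspace(0, 1, 100))
        combined = td.combine_traces([t, self._toy_trace(np.linspace(0, 1, 100), "u")])
        assert len(combined) == 180

    def test_combine_single_is_trimmed_identity(self):
        t = self._toy_trace(np.arange(50.0))
        c = td.combine_traces([t])
        assert len(c) == 45
        assert np.allclose(c.df["lambda_0"], np.arange(5.0, 50.0))

    def test_combined_mean_is_weighted_mean(self):
        a = self._toy_trace(np.full(100, 2.0), "a")
        b = self._toy_trace(np.full(300, 6.0), "b")
        c = td.combine_traces([a, b])
        assert c.df["lambda_0"].mean() == pytest.approx(
            (90 * 2 + 270 * 6) / 360)

    def test_combine_refuses_mixed_k(self):
        t1 = self._toy_trace(np.arange(10.0))
        df2 = t1.df.copy()
        df2["lambda_1"] = 1.0
        df2["mu_1"] = 1.0
        t2 = td.PosteriorTrace(df2, k=2, burn_in=0.1)
        with pytest.raises(ValueError, match="different k"):
            td.combine_traces([t1, t2])

    def test_net_diversification(self):
        t = self._toy_trace([0.2, 0.4])
        r = td.net_diversification(t)
        assert np.allclose(r["r_0"], [0.1, 0.2])


class TestHpd:
    def test_constant_samples_zero_width(self):
        lo, hi = td.hpd_interval(np.full(50, 3.3), 0.95)
        assert lo == hi == pytest.approx(3.3)

    def test_uniform_width(self):
        x = np.random.default_rng(0).uniform(size=10_000)
        lo, hi = td.hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_nesting(self):
        x = np.random.default_rng(1).normal(size=2_000)
        widths = [np.diff(td.hpd_interval(x, m))[0] for m in (0.80, 0.90, 0.95)]
        assert widths[0] <= widths[1] <= widths[2]

    def test_skewed_shorter_than_central(self):
        """HPD of an exponential hugs zero, unlike the equal-tail interval."""
        x = np.random.default_rng(2).exponential(size=5_000)
        lo, hi = td.hpd_interval(x, 0.9)
        assert lo < np.quantile(x, 0.05)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            td.hpd_interval([], 0.95)


class TestRateDifferences:
    def _trace_from(self, lam0, lam1):
        n = len(lam0)
        df = pd.DataFrame({
            "iter": np.arange(n), "tree_tag": "t", "loglik": 0.0,
            "logpost": 0.0,
            "lambda_0": lam0, "lambda_1": lam1,
            "mu_0": np.zeros(n), "mu_1": np.zeros(n),
            "q_0_1": np.ones(n), "q_1_0": np.ones(n),
            "s_lambda": 1.0, "s_mu": 1.0, "s_q": 1.0,
        })
        return td.PosteriorTrace(df, k=2)

    def test_identical_not_significant(self):
        x = np.random.default_rng(3).normal(1, 0.1, 500)
        comp = td.rate_differences(self._trace_from(x, x), focal=0)
        assert np.allclose(comp.differences["speciation"][1], 0.0)
        assert not any(comp.significant["speciation"][1].values())

    def test_constant_offset_significant(self):
        x = np.random.default_rng(4).normal(1, 0.1, 500)
        comp = td.rate_differences(self._trace_from(x, x + 1.0), focal=0)
        assert all(comp.significant["speciation"][1].values())

    def test_monte_carlo_separation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.1, 1500)
        b = rng.normal(0.5, 0.1, 1500)
        comp = td.rate_differences(self._trace_from(a, b), focal=0)
        assert comp.significant["speciation"][1][0.95]
        # difference of the two normals is N(0.5, 0.1*sqrt(2))
        lo, hi = comp.hpd["speciation"][1][0.95]
        assert lo == pytest.approx(0.5 - 1.96 * 0.1 * np.sqrt(2), abs=0.04)
        assert hi == pytest.approx(0.5 + 1.96 * 0.1 * np.sqrt(2), abs=0.04)

    def test_focal_validation(self):
        t = self._trace_from(np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            td.rate_differences(t, focal=5)
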