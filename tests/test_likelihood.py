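import numpy as np
import pytest

import trophodiv as td
from trophodiv.likelihood import OdeState, parameter_count
from trophodiv.reference import musse_loglik_rk4
from trophodiv.trees import Phylogeny

from conftest import random_yule_tree


class TestBranchIntegrate:
    def test_zero_duration_identity(self):
        p = td.MusseParameters([0.3, 0.2], [0.1, 0.1], [[0, 0.1], [0.1, 0]])
        s0 = OdeState(E=[0.1, 0.2], D=[0.5, 0.4])
        s1 = td.branch_integrate(s0, 0.0, p)
        assert np.allclose(s1.E, s0.E) and np.allclose(s1.D, s0.D)

    def test_all_rates_zero_identity(self):
        p = td.MusseParameters([0.0, 0.0], [0.0, 0.0], np.zeros((2, 2)))
        s0 = OdeState(E=[0.3, 0.6], D=[0.2, 0.9])
        s1 = td.branch_integrate(s0, 5.0, p)
        assert np.allclose(s1.E, s0.E) and np.allclose(s1.D, s0.D)

    def test_pure_extinction_closed_form(self):
        """k=1, lam=q=0: the system decouples and is linear."""
        mu, t, E0, D0 = 0.3, 2.0, 0.2, 0.7
        p = td.MusseParameters([0.0], [mu], [[0.0]])
        s1 = td.branch_integrate(OdeState(E=[E0], D=[D0]), t, p)
        assert s1.E[0] == pytest.approx(1 + (E0 - 1) * np.exp(-mu * t), abs=1e-8)
        assert s1.D[0] == pytest.approx(D0 * np.exp(-mu * t), abs=1e-8)

    def test_E_stays_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = int(rng.integers(1, 4))
            p = td.MusseParameters(rng.uniform(0, 1, k), rng.uniform(0, 1, k),
                                   rng.uniform(0, 0.5, (k, k)))
            s0 = OdeState(E=rng.uniform(0, 1, k), D=rng.uniform(0.1, 1, k))
            s1 = td.branch_integrate(s0, float(rng.uniform(0, 5)), p)
            assert np.all(s1.E >= 0) and np.all(s1.E <= 1)
            assert np.all(s1.D >= 0)


class TestMusseLoglik:
    def test_child_order_invariance(self, rng):
        tree = random_yule_tree(20, seed=3)
        k = 3
        states = td.TipStateMap(
            {t: int(rng.integers(k)) for t in tree.tip_labels}, k=k)
        p = td.MusseParameters(rng.uniform(0.1, 0.5, k),
                               rng.uniform(0.0, 0.2, k),
                               rng.uniform(0.01, 0.1, (k, k)))
        ll = td.musse_loglik(tree, states, p)
        flipped = Phylogeny(tree.right, tree.left, tree.blen, tree.labels)
        assert td.musse_loglik(flipped, states, p) == pytest.approx(ll, abs=1e-9)

    def test_tip_relabeling_invariance(self, rng):
        tree = random_yule_tree(15, seed=13)
        states = {t: int(rng.integers(2)) for t in tree.tip_labels}
        p = td.MusseParameters([0.3, 0.2], [0.05, 0.1], [[0, 0.05], [0.02, 0]])
        ll = td.musse_loglik(tree, td.TipStateMap(states, k=2), p)
        renames = {t: f"zz_{t}" for t in tree.tip_labels}
        tree2 = Phylogeny(tree.left, tree.right, tree.blen,
                          [renames.get(lb, lb) for lb in tree.labels])
        states2 = {renames[t]: s for t, s in states.items()}
        assert td.musse_loglik(tree2, td.TipStateMap(states2, k=2), p) == \
            pytest.approx(ll, abs=1e-12)

    def test_unreachable_state_mu_irrelevant(self, rng):
        """With all tips in state 0 and q=0, mu_1 cannot matter."""
        tree = random_yule_tree(12, seed=5)
        states = td.TipStateMap({t: 0 for t in tree.tip_labels}, k=2)
        base = dict(lam=[0.4, 0.3], q=np.zeros((2, 2)))
        ll1 = td.musse_loglik(tree, states,
                              td.MusseParameters(mu=[0.1, 0.05], **base))
        ll2 = td.musse_loglik(tree, states,
                              td.MusseParameters(mu=[0.1, 0.95], **base))
        assert ll1 == pytest.approx(ll2, abs=1e-7)

    def test_full_sampling_fraction_is_default(self, rng):
        tree = random_yule_tree(10, seed=6)
        states = td.TipStateMap(
            {t: int(rng.integers(2)) for t in tree.tip_labels}, k=2)
        p0 = td.MusseParameters([0.3, 0.2], [0.05, 0.1], [[0, 0.05], [0.02, 0]])
        p1 = td.MusseParameters([0.3, 0.2], [0.05, 0.1], [[0, 0.05], [0.02, 0]],
                                f=[1.0, 1.0])
        assert td.musse_loglik(tree, states, p0) == \
            td.musse_loglik(tree, states, p1)

    def test_unknown_tip_states_allowed(self, rng):
        tree = random_yule_tree(10, seed=61)
        labels = tree.tip_labels
        states = {t: int(rng.integers(2)) for t in labels}
        states[labels[0]] = None
        ll = td.musse_loglik(tree, td.TipStateMap(states, k=2),
                             td.MusseParameters([0.3, 0.2], [0.05, 0.1],
                                                [[0, 0.05], [0.02, 0]]))
        assert np.isfinite(ll)

    def test_impossible_data_minus_inf(self):
        tree = td.read_newick("(A:1.0,B:1.0);")
        states = td.TipStateMap({"A": 0, "B": 1}, k=2)
        # no transitions possible, so two different states cannot coexist
        p = td.MusseParameters([0.3, 0.3], [0.0, 0.0], np.zeros((2, 2)))
        assert td.musse_loglik(tree, states, p) == -np.inf

    def test_k_mismatch_raises(self, small_tree):
        states = td.TipStateMap({t: 0 for t in small_tree.tip_labels}, k=2)
        p = td.MusseParameters([0.3], [0.1], [[0.0]])
        with pytest.raises(td.TreeError):
            td.musse_loglik(small_tree, states, p)


class TestParameterCount:
    @pytest.mark.parametrize("k,hyper,expected", [
        (9, 3, 93), (1, 0, 2), (2, 3, 9),
    ])
    def test_counts(self, k, hyper, expected):
        assert parameter_count(k, hyper) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            parameter_count(0, 3)


def test_named_vector_round_trip():
    p = td.MusseParameters([0.3, 0.2], [0.05, 0.1], [[0, 0.07], [0.02, 0]])
    v = p.to_named_vector()
    assert v["q_0_1"] == pytest.approx(0.07)
    p2 = td.MusseParameters.from_named_vector(v, k=2)
    assert np.allclose(p2.lam, p.lam) and np.allclose(p2.q, p.q)
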