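import numpy as np
import pytest
from scipy.stats import spearmanr

import trophodiv as td
from trophodiv.simulate import tip_state_proportions

from conftest import random_yule_tree, simulate_surviving


def two_state_params(lam=(0.4, 0.3), mu=(0.05, 0.05), q=0.05):
    return td.MusseParameters(list(lam), list(mu), [[0, q], [q, 0]])


class TestTreeSimulation:
    def test_seed_reproducibility(self):
        cfg = td.SimulationConfig(two_state_params(), n_tips=50,
                                  root_state=0, seed=124)
        t1, s1 = td.simulate_musse_tree(cfg)
        t2, s2 = td.simulate_musse_tree(cfg)
        assert td.write_newick(t1) == td.write_newick(t2)
        assert dict(s1) == dict(s2)

    def test_stop_on_taxa_hits_target(self):
        tree, smap = simulate_surviving(two_state_params(), seed=5,
                                        n_tips=80, root_state=0)
        assert tree.n_tips == 80
        assert set(smap) == set(tree.tip_labels)

    def test_trees_pass_validation_and_are_ultrametric(self):
        for seed in range(5):
            tree, _ = simulate_surviving(two_state_params(), seed=seed,
                                         n_tips=40, root_state=0)
            assert np.all(tree.blen >= 0)
            assert tree.is_ultrametric(rel_tol=1e-8)

    def test_no_extinction_means_complete_equals_pruned(self):
        p = td.MusseParameters([0.5, 0.5], [0.0, 0.0], [[0, 0.1], [0.1, 0]])
        pruned, smap, complete = td.simulate_musse_tree(td.SimulationConfig(
            p, n_tips=40, root_state=0, seed=9, return_complete=True))
        assert pruned.n_tips == 40
        # complete tree only adds the stem lineage
        assert complete.n_tips == 40

    def test_lambda_zero_fails_with_fewer_than_two_tips(self):
        p = td.MusseParameters([0.0], [0.0], [[0.0]])
        with pytest.raises(td.TotalExtinctionError):
            td.simulate_musse_tree(td.SimulationConfig(
                p, max_time=1.0, root_state=0, seed=1))

    def test_yule_expected_tip_count(self):
        """Single stem lineage, lam=1, mu=0, T=1: E[N] = e."""
        p = td.MusseParameters([1.0], [0.0], [[0.0]])
        counts = []
        for seed in range(1500):
            try:
                tree, _ = td.simulate_musse_tree(td.SimulationConfig(
                    p, max_time=1.0, root_state=0, seed=seed))
                counts.append(tree.n_tips)
            except td.TotalExtinctionError:
                counts.append(1)  # unbranched stem: one lineage at T
        m = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(m - np.e) < 3 * se + 1e-9

    def test_high_symmetric_q_uniform_tip_states(self):
        p = td.MusseParameters([0.5, 0.5], [0.0, 0.0], [[0, 3.0], [3.0, 0]])
        fracs = []
        for seed in range(40):
            _, smap = td.simulate_musse_tree(td.SimulationConfig(
                p, n_tips=60, root_state=0, seed=seed))
            fracs.append(tip_state_proportions(smap)[0])
        m, se = np.mean(fracs), np.std(fracs) / np.sqrt(len(fracs))
        assert abs(m - 0.5) < 3 * se + 0.02

    def test_exactly_one_stop_rule(self):
        with pytest.raises(ValueError):
            td.SimulationConfig(two_state_params(), n_tips=10, max_time=1.0)
        with pytest.raises(ValueError):
            td.SimulationConfig(two_state_params())


class TestMkSimulation:
    def test_zero_rates_inherit_root_state(self, yule_200):
        smap = td.simulate_mk_character(yule_200, np.zeros((3, 3)),
                                        root_state=2, seed=1)
        assert set(smap.values()) == {2}

    def test_long_branch_stationary_frequency(self):
        tree = td.read_newick("(A:60.0,B:60.0);")
        q = np.array([[0, 1.0], [1.0, 0]])
        hits = []
        for seed in range(400):
            smap = td.simulate_mk_character(tree, q, root_state=0, seed=seed)
            hits += [smap["A"], smap["B"]]
        assert np.mean(hits) == pytest.approx(0.5, abs=0.05)

    def test_state_correlation_decays_with_distance(self, yule_200):
        q = np.array([[0, 0.3], [0.3, 0]])
        labels, dmat = yule_200.patristic_distances()
        rng = np.random.default_rng(12)
        dists, agree = [], []
        for seed in range(25):
            smap = td.simulate_mk_character(yule_200, q, root_state=0,
                                            seed=seed)
            for _ in range(80):
                i, j = rng.integers(len(labels)), rng.integers(len(labels))
                if i == j:
                    continue
                dists.append(dmat[i, j])
                agree.append(int(smap[labels[i]] == smap[labels[j]]))
        rho, _ = spearmanr(dists, agree)
        assert rho < 0


class TestAdequacy:
    def test_single_tree_envelope_is_that_tree(self):
        p = two_state_params()
        res = td.adequacy_test(p, 1, [0.5, 0.5], n_tips=40,
                               root_state=0, seed=3)
        assert np.allclose(res.envelope_low, res.envelope_high)
        assert np.allclose(res.envelope_low, res.proportions[0])

    def test_impossible_state_outside_envelope(self):
        # state 1 cannot persist: no speciation, heavy extinction
        p = td.MusseParameters([0.5, 0.0], [0.0, 1.0], [[0, 0.01], [0, 0]])
        res = td.adequacy_test(p, 30, [0.0, 1.0], n_tips=30,
                               root_state=0, seed=4)
        assert not res.inside[1]

    def test_rows_sum_to_one(self):
        res = td.adequacy_test(two_state_params(), 10, [0.5, 0.5],
                               n_tips=30, root_state=0, seed=5)
        assert np.allclose(res.proportions.sum(axis=1), 1.0)


class TestNeutralAssociation:
    def test_constrained_model_never_flags(self):
        p = two_state_params()
        tree, _ = simulate_surviving(p, seed=21, n_tips=50, root_state=0)
        q_hat = np.array([[0, 0.3], [0.3, 0]])
        cfg = td.McmcConfig(steps=60, thin=3, burn_in=0.2, seed=2)
        records, frac = td.neutral_association_test(
            [tree], q_hat, cfg, seed=3, constrain_equal_rates=True)
        assert frac == 0.0
        assert not records[0]["flagged"]

    def test_empty_tree_list_errors(self):
        with pytest.raises(ValueError):
            td.neutral_association_test([], np.zeros((2, 2)),
                                        td.McmcConfig(steps=10, thin=1))

    def test_smoke_unconstrained(self):
        tree, _ = simulate_surviving(two_state_params(), seed=31,
                                     n_tips=40, root_state=0)
        q_hat = np.array([[0, 0.2], [0.2, 0]])
        cfg = td.McmcConfig(steps=40, thin=2, burn_in=0.2, seed=4)
        records, frac = td.neutral_association_test([tree], q_hat, cfg, seed=5)
        assert records[0]["skipped"] in (False, True)
        assert 0.0 <= frac <= 1.0 or np.isnan(frac)
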