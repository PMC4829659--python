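import numpy as np
import pandas as pd
import pytest

import trophodiv as td
from trophodiv.network import _power_iteration_batch


def make_trace(qvals, n=50):
    """Constant-valued trace with k inferred from the q dict."""
    k = max(max(i, j) for i, j in qvals) + 1
    cols = {"iter": np.arange(n), "tree_tag": "t", "loglik": 0.0,
            "logpost": 0.0}
    for i in range(k):
        cols[f"lambda_{i}"] = 0.3
        cols[f"mu_{i}"] = 0.1
    for (i, j), v in qvals.items():
        cols[f"q_{i}_{j}"] = v
    cols.update({"s_lambda": 1.0, "s_mu": 1.0, "s_q": 1.0})
    return td.PosteriorTrace(pd.DataFrame(cols), k=k)


class TestBuildNetwork:
    def test_constant_trace_gives_constants(self):
        qv = {(0, 1): 0.2, (1, 0): 0.05, (0, 2): 0.1, (2, 0): 0.01,
              (1, 2): 0.3, (2, 1): 0.02}
        net = td.build_network(make_trace(qv), ["a", "b", "c"])
        for (i, j), v in qv.items():
            assert net.w[i, j] == pytest.approx(v)
        assert np.all(np.diag(net.w) == 0)

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        tr = make_trace({(0, 1): 0.1, (1, 0): 0.1})
        vals = rng.exponential(0.1, len(tr.df))
        tr.df["q_0_1"] = vals
        net = td.build_network(tr, ["a", "b"])
        s = np.sort(vals)
        oracle = 0.5 * (s[len(s) // 2 - 1] + s[len(s) // 2])
        assert net.w[0, 1] == pytest.approx(oracle)

    def test_median_permutation_invariant(self):
        rng = np.random.default_rng(1)
        tr = make_trace({(0, 1): 0.1, (1, 0): 0.1})
        vals = rng.exponential(0.1, len(tr.df))
        tr.df["q_0_1"] = vals
        w1 = td.build_network(tr, ["a", "b"]).w[0, 1]
        tr.df["q_0_1"] = rng.permutation(vals)
        w2 = td.build_network(tr, ["a", "b"]).w[0, 1]
        assert w1 == pytest.approx(w2)

    def test_cutoff_affects_display_only(self):
        net = td.TransitionNetwork(["a", "b"], [[0, 0.0005], [0.5, 0]],
                                   display_cutoff=0.001)
        assert net.w[0, 1] == pytest.approx(0.0005)
        assert net.display_matrix()[0, 1] == 0.0


class TestEigenvectorCentrality:
    def test_complete_equal_weights(self):
        w = np.ones((4, 4)) - np.eye(4)
        c = td.eigenvector_centrality(td.TransitionNetwork(list("abcd"), w))
        assert np.allclose(c, 1.0)

    def test_three_cycle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = w[2, 0] = 1.0
        c = td.eigenvector_centrality(td.TransitionNetwork(list("abc"), w))
        assert np.allclose(c, 1.0, atol=1e-9)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = rng.uniform(0.1, 1.0, (4, 4))
            np.fill_diagonal(w, 0.0)
            c = td.eigenvector_centrality(td.TransitionNetwork(list("abcd"), w))
            vals, vecs = np.linalg.eig(w.T)
            lead = np.abs(vecs[:, np.argmax(vals.real)].real)
            assert np.allclose(c, lead / lead.max(), atol=1e-8)

    def test_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(8)
        w = rng.uniform(0.1, 1.0, (5, 5))
        np.fill_diagonal(w, 0.0)
        c = td.eigenvector_centrality(td.TransitionNetwork(list("abcde"), w))
        g = nx.DiGraph()
        for i in range(5):
            for j in range(5):
                if i != j:
                    g.add_edge(i, j, weight=w[i, j])
        ref = nx.eigenvector_centrality(g, weight="weight", max_iter=2000,
                                        tol=1e-12)
        ref = np.array([ref[i] for i in range(5)])
        assert np.allclose(c, ref / ref.max(), atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        w = rng.uniform(0.1, 1.0, (4, 4))
        np.fill_diagonal(w, 0.0)
        c1 = td.eigenvector_centrality(td.TransitionNetwork(list("abcd"), w))
        c2 = td.eigenvector_centrality(td.TransitionNetwork(list("abcd"), 7.3 * w))
        assert np.allclose(c1, c2, atol=1e-10)

    def test_symmetric_matches_undirected(self):
        rng = np.random.default_rng(10)
        w = rng.uniform(0.1, 1.0, (4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        c = td.eigenvector_centrality(td.TransitionNetwork(list("abcd"), w))
        vals, vecs = np.linalg.eigh(w)
        lead = np.abs(vecs[:, -1])
        assert np.allclose(c, lead / lead.max(), atol=1e-8)

    def test_no_positive_weight_errors(self):
        with pytest.raises(ValueError):
            td.eigenvector_centrality(
                td.TransitionNetwork(["a", "b"], np.zeros((2, 2))))


class TestPermutationTest:
    def test_identical_weights_p_one(self):
        w = 0.3 * (np.ones((4, 4)) - np.eye(4))
        res = td.centrality_permutation_test(
            td.TransitionNetwork(list("abcd"), w), n_perm=200, seed=1)
        assert np.allclose(res.p_values, 1.0)
        assert np.allclose(res.centrality, 1.0)

    def test_star_hub_detected(self):
        """Heavy weights converging on one hub: small hub p, large spoke p."""
        k = 6
        w = np.full((k, k), 0.01)
        np.fill_diagonal(w, 0.0)
        w[1:, 0] = 1.0
        res = td.centrality_permutation_test(
            td.TransitionNetwork(list("abcdef"), w), n_perm=1000, seed=2)
        assert np.argmax(res.centrality) == 0
        assert res.p_values[0] < 0.02
        assert np.all(res.p_values[1:] > 0.2)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        w = rng.uniform(0.1, 1.0, (4, 4))
        np.fill_diagonal(w, 0.0)
        perm = np.array([2, 0, 3, 1])
        wp = w[np.ix_(perm, perm)]
        r1 = td.centrality_permutation_test(
            td.TransitionNetwork(list("abcd"), w), n_perm=500, seed=3)
        r2 = td.centrality_permutation_test(
            td.TransitionNetwork(list("abcd"), wp), n_perm=500, seed=3)
        assert np.allclose(r1.centrality[perm], r2.centrality, atol=1e-9)

    def test_nperm_validation(self):
        net = td.TransitionNetwork(["a", "b"], [[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            td.centrality_permutation_test(net, n_perm=0)


def test_batch_power_iteration_agrees_with_single():
    rng = np.random.default_rng(12)
    stack = rng.uniform(0.05, 1.0, (6, 5, 5))
    for b in range(6):
        np.fill_diagonal(stack[b], 0.0)
    batch, _ = _power_iteration_batch(stack)
    for b in range(6):
        single, _ = _power_iteration_batch(stack[b][None])
        assert np.allclose(batch[b], single[0], atol=1e-9)
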