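import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import brute_aracne, brute_ols
from protpred.bayes_net import (FitFailure, MIMatrix, aracne_skeleton,
                                bn_predict, bn_train_predict, build_mi_matrix,
                                fit_gaussian_bn, gaussian_mi,
                                mi_significance_threshold, orient_to_dag)
from protpred.data_io import ValidationError, substream
from protpred.preprocess import TranscriptSelection


def _mi_matrix(values, n=1000):
    values = np.asarray(values, dtype=float)
    k = values.shape[0]
    return MIMatrix([f"n{i}" for i in range(k)], values,
                    np.full((k, k), n, dtype=int))


class TestGaussianMI:
    def test_closed_form_at_r_0_6(self):
        # construct exact r = 0.6 via two orthogonal unit-variance pieces
        n = 400
        rng = substream(0, "mi")
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        y = 0.6 * a + math.sqrt(1 - 0.36) * b
        assert gaussian_mi(a, y) == pytest.approx(-0.5 * math.log(0.64),
                                                  abs=1e-9)
        assert gaussian_mi(a, y) == pytest.approx(0.22314, abs=1e-4)

    def test_identical_vectors_hit_ceiling(self, rng):
        x = rng.standard_normal(50)
        assert gaussian_mi(x, x) == pytest.approx(-0.5 * math.log1p(-(1 - 1e-12) ** 2))

    def test_independent_vectors_near_zero(self):
        rng = substream(1, "mi_indep")
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        assert gaussian_mi(x, y) < 0.01

    def test_too_few_pairs_error(self):
        with pytest.raises(ValidationError):
            gaussian_mi(np.array([1.0, 2.0]), np.array([3.0, 4.0]))

    def test_build_matrix_symmetric_nonnegative(self, rng):
        data = pd.DataFrame(rng.standard_normal((50, 4)))
        data.columns = list("abcd")
        mi = build_mi_matrix(data)  # __post_init__ asserts the invariants
        assert (mi.values >= 0).all()
        assert np.allclose(mi.values, mi.values.T)


class TestAracneSkeleton:
    def test_chain_removes_indirect_edge(self):
        rng = substream(2, "chain")
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        y = 0.9 * x2 + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        mi = build_mi_matrix(pd.DataFrame({"x1": x1, "x2": x2, "y": y}))
        edges = aracne_skeleton(mi)
        assert frozenset(("x1", "x2")) in edges
        assert frozenset(("x2", "y")) in edges
        assert frozenset(("x1", "y")) not in edges

    def test_matches_bruteforce_on_random_4node_matrices(self, rng):
        for _ in range(25):
            raw = np.abs(rng.standard_normal((4, 4)))
            mi_vals = np.triu(raw, 1)
            mi_vals = mi_vals + mi_vals.T
            mi = _mi_matrix(mi_vals)
            got = aracne_skeleton(mi, p_filter=None)
            expect = brute_aracne(mi_vals)
            expect_named = {frozenset((f"n{i}", f"n{j}")) for i, j in expect}
            assert got == expect_named

    def test_all_independent_nodes_yield_empty_graph(self):
        rng = substream(3, "indep3")
        data = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        mi = build_mi_matrix(data)
        # significance pre-filter clears the noise edges the strict-minimum
        # DPI rule would otherwise keep under ties
        assert aracne_skeleton(mi, p_filter=0.05) == set()

    def test_dpi_never_removes_strict_triangle_maximum(self, rng):
        for _ in range(10):
            raw = np.abs(rng.standard_normal((5, 5))) + 0.1
            mi_vals = np.triu(raw, 1)
            mi_vals = mi_vals + mi_vals.T
            mi = _mi_matrix(mi_vals)
            kept = aracne_skeleton(mi, p_filter=None)
            # an edge that is the strict maximum of EVERY triangle containing
            # it can never be marked by the DPI and must survive
            for i, j in itertools.combinations(range(5), 2):
                others = [m for m in range(5) if m not in (i, j)]
                if all(mi_vals[i, j] > max(mi_vals[i, m], mi_vals[j, m])
                       for m in others):
                    assert frozenset((f"n{i}", f"n{j}")) in kept

    def test_significance_threshold_decreases_with_n(self):
        assert mi_significance_threshold(50) > mi_significance_threshold(500)
        assert mi_significance_threshold(2) == math.inf


class TestOrientation:
    def test_star_points_into_protein(self):
        nodes = ["p", "t1", "t2", "t3"]
        skeleton = {frozenset(("p", t)) for t in nodes[1:]}
        dag = orient_to_dag(skeleton, "p", nodes)
        assert set(dag.edges) == {("t1", "p"), ("t2", "p"), ("t3", "p")}

    def test_empty_skeleton_empty_dag(self):
        dag = orient_to_dag(set(), "p", ["p", "t1"])
        assert len(dag.edges) == 0 and set(dag.nodes) == {"p", "t1"}

    def test_random_skeletons_always_acyclic(self, rng):
        nodes = [f"n{i}" for i in range(9)]
        pairs = list(itertools.combinations(nodes, 2))
        for _ in range(50):
            chosen = [frozenset(p) for p in pairs if rng.random() < 0.4]
            dag = orient_to_dag(set(chosen), "n0", nodes)
            assert nx.is_directed_acyclic_graph(dag)


class TestFitGaussianBN:
    def test_parentless_node_gets_mean_and_sd(self, rng):
        y = rng.standard_normal(40)
        dag = orient_to_dag(set(), "p", ["p"])
        net = fit_gaussian_bn(dag, pd.DataFrame({"p": y}))
        assert net.nodes["p"].intercept == pytest.approx(y.mean())
        assert net.nodes["p"].residual_sd == pytest.approx(y.std(ddof=1))

    def test_noiseless_linear_child(self, rng):
        x = rng.standard_normal(30)
        data = pd.DataFrame({"x": x, "y": 0.5 * x})
        dag = orient_to_dag({frozenset(("x", "y"))}, "y", ["x", "y"])
        net = fit_gaussian_bn(dag, data)
        p = net.nodes["y"]
        assert p.coefficients[0] == pytest.approx(0.5, abs=1e-10)
        assert p.intercept == pytest.approx(0.0, abs=1e-10)
        assert p.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((25, 2))
        y = 1.0 + 0.7 * X[:, 0] - 0.3 * X[:, 1] + 0.1 * rng.standard_normal(25)
        data = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "y": y})
        skeleton = {frozenset(("a", "y")), frozenset(("b", "y"))}
        dag = orient_to_dag(skeleton, "y", ["a", "b", "y"])
        net = fit_gaussian_bn(dag, data)
        expect = brute_ols(X, y)
        assert net.nodes["y"].intercept == pytest.approx(expect[0], abs=1e-9)
        assert np.allclose(net.nodes["y"].coefficients, expect[1:], atol=1e-9)

    def test_insufficient_complete_rows_fail(self, rng):
        data = pd.DataFrame({"x": [1.0, np.nan, 3.0], "y": [1.0, 2.0, np.nan]})
        dag = orient_to_dag({frozenset(("x", "y"))}, "y", ["x", "y"])
        with pytest.raises(FitFailure):
            fit_gaussian_bn(dag, data)

    def test_rank_deficiency_fails(self, rng):
        x = rng.standard_normal(20)
        data = pd.DataFrame({"a": x, "b": x, "y": x})
        skeleton = {frozenset(("a", "y")), frozenset(("b", "y"))}
        dag = orient_to_dag(skeleton, "y", ["a", "b", "y"])
        with pytest.raises(FitFailure):
            fit_gaussian_bn(dag, data)


class TestBNPredict:
    def _single_parent_net(self, rng):
        x = rng.standard_normal(40)
        data = pd.DataFrame({"x": x, "y": 0.5 * x})
        dag = orient_to_dag({frozenset(("x", "y"))}, "y", ["x", "y"])
        return fit_gaussian_bn(dag, data)

    def test_parentless_target_training_mean(self, rng):
        y = rng.standard_normal(30)
        dag = orient_to_dag(set(), "p", ["p"])
        net = fit_gaussian_bn(dag, pd.DataFrame({"p": y}))
        value, status = bn_predict(net, "p", {})
        assert status == "degenerate"
        assert value == pytest.approx(y.mean())

    def test_linear_evaluation(self, rng):
        net = self._single_parent_net(rng)
        value, status = bn_predict(net, "y", {"x": 2.0})
        assert status == "ok"
        assert value == pytest.approx(1.0, abs=1e-9)

    def test_batch_prediction_matches_per_row(self, rng):
        from protpred.bayes_net import bn_predict_batch
        net = self._single_parent_net(rng)
        X = pd.DataFrame({"x": [0.5, np.nan, -2.0]})
        batch = bn_predict_batch(net, "y", X)
        single = [bn_predict(net, "y", row)[0] for _, row in X.iterrows()]
        assert np.allclose(batch, single)

    def test_missing_parent_imputed_with_training_mean(self, rng):
        net = self._single_parent_net(rng)
        value, _ = bn_predict(net, "y", {"x": np.nan})
        p = net.nodes["y"]
        expect = p.intercept + p.coefficients[0] * net.train_means["x"]
        assert value == pytest.approx(expect)

    def test_scale_consistency(self, rng):
        # z-score inputs then predict == predict then z-score (linear model)
        x = rng.standard_normal(60)
        y = 0.8 * x + 0.2 * rng.standard_normal(60)
        data = pd.DataFrame({"x": x, "y": y})
        dag = orient_to_dag({frozenset(("x", "y"))}, "y", ["x", "y"])
        net = fit_gaussian_bn(dag, data)
        mz = (data - data.mean()) / data.std(ddof=1)
        netz = fit_gaussian_bn(dag, mz)
        queries = np.linspace(-2, 2, 9)
        raw = np.array([bn_predict(net, "y", {"x": q})[0] for q in queries])
        scaled_queries = (queries - data["x"].mean()) / data["x"].std(ddof=1)
        z = np.array([bn_predict(netz, "y", {"x": q})[0]
                      for q in scaled_queries])
        assert np.allclose((raw - data["y"].mean()) / data["y"].std(ddof=1),
                           z, atol=1e-8)


class TestBNTrainPredict:
    def test_end_to_end_recovers_direct_parent(self, rng):
        n = 300
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        y = 0.9 * x2 + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        X = pd.DataFrame({"x1": x1, "x2": x2},
                         index=[f"s{i}" for i in range(n)])
        sel = TranscriptSelection("p", ("x2", "x1"), (0.9, 0.81))
        y_tr = pd.Series(y, index=X.index, name="p")
        test_pred, train_pred, status, net = bn_train_predict(
            X.iloc[:250], y_tr.iloc[:250], X.iloc[250:], sel)
        assert status == "ok"
        assert net.nodes["p"].parents == ["x2"]
        r = np.corrcoef(test_pred, y[250:])[0, 1]
        assert r > 0.7
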