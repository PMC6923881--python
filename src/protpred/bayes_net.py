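"""ARACNE-pruned Gaussian Bayesian networks for protein prediction.

Per protein, a small network is learned over {protein} + its selected
transcripts: pairwise Gaussian mutual information gives a weighted complete
graph, edges failing a Gaussian independence test are dropped, ARACNE's
data-processing-inequality scan removes the weakest edge of every fully
connected triple, the skeleton is oriented into a DAG (transcript edges
point into the protein; the rest follow the canonical node order), and each
node is fit by ordinary least squares on its parents over complete training
rows. Prediction for the protein is its linear-Gaussian conditional mean
given the test sample's parent values, with missing parents imputed by
their training means.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ValidationError

MI_CEILING_R = 1.0 - 1e-12  # |r| clip so MI stays finite


class FitFailure(RuntimeError):
    """Raised when a network cannot be fit (too few complete rows, rank
    deficiency); callers record this as a failed prediction."""


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (nats) under a bivariate-Gaussian model:
    MI = -0.5 ln(1 - r^2), r the pairwise-complete Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vector length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValidationError("need >= 3 complete pairs for MI")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(-MI_CEILING_R, min(MI_CEILING_R, r))
    return -0.5 * math.log1p(-r * r)


@dataclass
class MIMatrix:
    """Symmetric pairwise mutual information over the network's nodes."""

    node_ids: list[str]
    values: np.ndarray       # MI in nats, zero diagonal
    n_pairs: np.ndarray      # complete-pair counts behind each entry

    def __post_init__(self) -> None:
        k = len(self.node_ids)
        if self.values.shape != (k, k):
            raise ValidationError("MI matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("MI matrix must be symmetric")
        if (self.values < 0).any():
            raise ValidationError("MI entries must be >= 0")
        if np.diag(self.values).any():
            raise ValidationError("MI diagonal must be zero")


def build_mi_matrix(data: pd.DataFrame) -> MIMatrix:
    """Pairwise Gaussian MI over all columns of ``data`` (pairwise-complete)."""
    cols = list(data.columns)
    k = len(cols)
    mi = np.zeros((k, k))
    n_pairs = np.zeros((k, k), dtype=int)
    arr = data.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(k), 2):
        ok = ~(np.isnan(arr[:, i]) | np.isnan(arr[:, j]))
        n = int(ok.sum())
        n_pairs[i, j] = n_pairs[j, i] = n
        if n >= 3:
            mi[i, j] = mi[j, i] = gaussian_mi(arr[:, i], arr[:, j])
    return MIMatrix(node_ids=cols, values=mi, n_pairs=n_pairs)


def mi_significance_threshold(n: int, p: float = 0.05) -> float:
    """MI below this is indistinguishable from independence at level ``p``:
    the Gaussian deviance 2 n MI is asymptotically chi-square(1)."""
    if n < 3:
        return math.inf
    return float(stats.chi2.ppf(1.0 - p, df=1) / (2.0 * n))


def aracne_skeleton(
    mi: MIMatrix, p_filter: float | None = 0.05, dpi_epsilon: float = 0.0
) -> set[frozenset[str]]:
    """ARACNE: significance pre-filter then the data-processing-inequality scan.

    Starting from all significant edges, every fully connected node triple
    marks its strictly weakest edge (MI smaller than both others by more than
    ``dpi_epsilon``); marked edges are removed simultaneously after scanning
    all triples against the original MI values. The pre-filter (drop edges
    whose MI is insignificant at level ``p_filter``) also resolves the
    all-independent tie case, where DPI alone would keep a complete graph.
    """
    k = len(mi.node_ids)
    present = np.ones((k, k), dtype=bool)
    np.fill_diagonal(present, False)
    if p_filter is not None:
        for i, j in itertools.combinations(range(k), 2):
            thr = mi_significance_threshold(int(mi.n_pairs[i, j]), p_filter)
            if mi.values[i, j] < thr:
                present[i, j] = present[j, i] = False
    marked = np.zeros((k, k), dtype=bool)
    for a, b, c in itertools.combinations(range(k), 3):
        if not (present[a, b] and present[b, c] and present[a, c]):
            continue
        edges = [(a, b), (b, c), (a, c)]
        vals = [mi.values[i, j] for i, j in edges]
        order = np.argsort(vals)
        lo, mid = vals[order[0]], vals[order[1]]
        if lo < mid - dpi_epsilon:  # strict minimum only
            i, j = edges[order[0]]
            marked[i, j] = marked[j, i] = True
    keep = present & ~marked
    return {
        frozenset((mi.node_ids[i], mi.node_ids[j]))
        for i, j in itertools.combinations(range(k), 2)
        if keep[i, j]
    }


def orient_to_dag(
    skeleton: set[frozenset[str]], target: str, node_order: list[str]
) -> nx.DiGraph:
    """Orient the skeleton: edges at the target point into it, the rest run
    from lower to higher canonical node index — acyclic by construction."""
    rank = {node: i for i, node in enumerate(node_order)}
    dag = nx.DiGraph()
    dag.add_nodes_from(node_order)
    for edge in skeleton:
        u, v = sorted(edge, key=lambda n: rank[n])
        if target in edge:
            other = v if u == target else u
            dag.add_edge(other, target)
        else:
            dag.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(dag):  # cannot happen; cheap to assert
        raise ValidationError("orientation produced a cycle")
    return dag


@dataclass
class NodeParams:
    parents: list[str]
    intercept: float
    coefficients: np.ndarray
    residual_sd: float


@dataclass
class GaussianNetwork:
    """A fitted linear-Gaussian Bayesian network."""

    dag: nx.DiGraph
    nodes: dict[str, NodeParams]
    train_means: dict[str, float]  # for imputing missing parent values
    n_complete: int

    def to_json_dict(self) -> dict:
        return {
            "nodes": sorted(self.dag.nodes),
            "edges": sorted((u, v) for u, v in self.dag.edges),
            "n_complete": self.n_complete,
            "parameters": {
                node: {
                    "parents": p.parents,
                    "intercept": p.intercept,
                    "coefficients": list(map(float, p.coefficients)),
                    "residual_sd": p.residual_sd,
                }
                for node, p in sorted(self.nodes.items())
            },
        }


def fit_gaussian_bn(dag: nx.DiGraph, train: pd.DataFrame) -> GaussianNetwork:
    """OLS fit of every node on its parents over complete training rows.

    "Complete" means complete in all network variables, mirroring fitting a
    joint Gaussian on complete cases. Raises :class:`FitFailure` when there
    are fewer complete rows than max(parent count) + 2 or a node's design
    matrix is rank deficient.
    """
    cols = list(dag.nodes)
    complete = train[cols].dropna()
    max_parents = max((dag.in_degree(n) for n in cols), default=0)
    if len(complete) < max_parents + 2:
        raise FitFailure(
            f"{len(complete)} complete rows < {max_parents + 2} required")
    nodes: dict[str, NodeParams] = {}
    for node in cols:
        parents = sorted(dag.predecessors(node))
        y = complete[node].to_numpy(dtype=float)
        if not parents:
            sd = y.std(ddof=1) if len(y) > 1 else 0.0
            nodes[node] = NodeParams([], float(y.mean()), np.empty(0), float(sd))
            continue
        X = np.column_stack([np.ones(len(complete)),
                             complete[parents].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FitFailure(f"rank-deficient design for node {node}")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(1, len(y) - X.shape[1])
        sd = math.sqrt(float(resid @ resid) / dof)
        nodes[node] = NodeParams(parents, float(beta[0]), beta[1:], sd)
    means = {c: float(complete[c].mean()) for c in cols}
    return GaussianNetwork(dag=dag, nodes=nodes, train_means=means,
                           n_complete=len(complete))


def bn_predict(
    network: GaussianNetwork, target: str, test_values: pd.Series | dict
) -> tuple[float, str]:
    """Conditional mean of the target given its parents' test values.

    Missing parent values are imputed with the parent's training mean. A
    parentless target degenerates to its training mean.
    """
    if target not in network.nodes:
        raise ValidationError(f"{target!r} not in fitted network")
    params = network.nodes[target]
    if not params.parents:
        return params.intercept, "degenerate"
    vals = []
    for parent in params.parents:
        v = test_values[parent] if parent in test_values else np.nan
        v = float(v)
        if np.isnan(v):
            v = network.train_means[parent]
        vals.append(v)
    return float(params.intercept + np.dot(params.coefficients, vals)), "ok"


def bn_predict_batch(
    network: GaussianNetwork, target: str, X: pd.DataFrame
) -> np.ndarray:
    """Vectorized :func:`bn_predict` over the rows of ``X``."""
    params = network.nodes[target]
    if not params.parents:
        return np.full(len(X), params.intercept)
    P = X[params.parents].to_numpy(dtype=float).copy()
    for j, parent in enumerate(params.parents):
        col = P[:, j]
        col[np.isnan(col)] = network.train_means[parent]
    return params.intercept + P @ params.coefficients


def bn_train_predict(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    selection,
    p_filter: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, str, GaussianNetwork | None]:
    """Full per-protein pipeline: MI, ARACNE, orientation, fit, predict.

    Returns (test predictions, training predictions, status, network); on
    fit failure predictions are NaN and status is "failed".
    """
    target = str(y_train.name) if y_train.name is not None else "__protein__"
    cols = list(selection.transcript_ids)
    data = X_train[cols].copy()
    data[target] = y_train.to_numpy(dtype=float)
    node_order = [target] + cols
    data = data[node_order]
    try:
        mi = build_mi_matrix(data)
        skeleton = aracne_skeleton(mi, p_filter=p_filter)
        dag = orient_to_dag(skeleton, target, node_order)
        network = fit_gaussian_bn(dag, data)
    except (FitFailure, ValidationError):
        nan_te = np.full(len(X_test), np.nan)
        nan_tr = np.full(len(X_train), np.nan)
        return nan_te, nan_tr, "failed", None
    status = "degenerate" if not network.nodes[target].parents else "ok"
    test_pred = bn_predict_batch(network, target, X_test)
    train_pred = bn_predict_batch(network, target, X_train)
    return test_pred, train_pred, status, network
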