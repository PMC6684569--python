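"""Whole-brain graph analysis.

Subject connectivity matrices are full Pearson correlation matrices over
node time series.  Binary undirected graphs are defined by a strict
positive threshold on r (negative correlations never form edges), swept
over r = 0.20, 0.25, 0.30, 0.35, 0.40, and a battery of topology metrics
is computed per graph: characteristic path length, global efficiency,
mean degree, mean betweenness, Louvain modularity Q, and the hierarchy
exponent beta.

Conventions for disconnected graphs (path length over reachable pairs
only, with the unreachable-pair count reported) and for betweenness
normalization (fraction of geodesics per source-target pair, so the
centre of a maximal star scores 1) are recorded in the returned objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.stats import linregress

from .confounds import NodeTimeSeries
from .exceptions import DegenerateInputError, ParameterError, UndefinedMetricError

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.20, 0.25, 0.30, 0.35, 0.40)
_Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N Pearson correlations with Fisher-z companion.

    ``z_values`` has a zero diagonal — self-connections are excluded from
    every summary.
    """

    r_values: np.ndarray
    node_order: tuple[str, ...] | None = None
    z_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise DegenerateInputError(f"connectivity must be square, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise DegenerateInputError("connectivity matrix must be symmetric")
        object.__setattr__(self, "r_values", r)
        z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
        np.fill_diagonal(z, 0.0)
        object.__setattr__(self, "z_values", z)

    @property
    def n_nodes(self) -> int:
        return self.r_values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal, from a strict r threshold."""

    adjacency: np.ndarray
    threshold_r: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        a = (a != 0).astype(np.uint8)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DegenerateInputError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise DegenerateInputError("adjacency must be symmetric")
        np.fill_diagonal(a, 0)
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


@dataclass(frozen=True)
class GraphMetrics:
    threshold_r: float
    path_length: float
    global_efficiency: float
    mean_degree: float
    mean_betweenness: float
    mean_betweenness_raw: float
    modularity_q: float
    hierarchy_beta: float
    n_components: int
    n_unreachable_pairs: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_connectivity(
    ts: NodeTimeSeries, node_order: tuple[str, ...] | None = None
) -> ConnectivityMatrix:
    """Full Pearson correlation matrix between all node pairs."""
    X = ts.values
    if X.shape[0] < 3:
        raise DegenerateInputError("need at least 3 time points for correlations")
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (
            [node_order[i] for i in bad[:5]] if node_order else bad[:5].tolist()
        )
        raise DegenerateInputError(
            f"constant time series at node(s) {names}: correlation undefined"
        )
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, node_order)


def threshold_graph(conn: ConnectivityMatrix, threshold_r: float) -> BinaryGraph:
    """Edge iff r > threshold (strict); ties at the threshold are excluded."""
    if not (0.0 < threshold_r < 1.0):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold_r}")
    adj = (conn.r_values > threshold_r).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryGraph(adj, threshold_r)


def _distances(g: BinaryGraph) -> np.ndarray:
    return shortest_path(g.adjacency, method="D", unweighted=True, directed=False)


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean geodesic distance over reachable ordered pairs.

    Unreachable pairs are excluded from the mean (their count is available
    via :func:`graph_metrics`); raises if no pair is reachable.
    """
    cpl, _ = _path_length_with_count(g)
    return cpl


def _path_length_with_count(g: BinaryGraph) -> tuple[float, int]:
    if g.n_nodes < 2:
        raise UndefinedMetricError("path length needs at least 2 nodes")
    d = _distances(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise UndefinedMetricError("no reachable node pairs: path length undefined")
    return float(d[finite].mean()), n_unreachable


def global_efficiency(g: BinaryGraph) -> float:
    """Mean of 1/d over ordered node pairs, with 1/inf = 0."""
    if g.n_nodes < 2:
        raise UndefinedMetricError("global efficiency needs at least 2 nodes")
    d = _distances(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def mean_degree(g: BinaryGraph) -> float:
    """Mean number of connections per node."""
    return float(g.adjacency.sum(axis=1).mean())


def mean_betweenness(g: BinaryGraph, normalized: bool = True) -> float:
    """Mean betweenness centrality over nodes.

    Normalized form: for each node, the fraction of geodesics between all
    other node pairs that pass through it (ties split fractionally), so a
    maximal star's centre scores 1 and any complete graph scores 0.
    """
    if g.n_nodes < 3:
        raise UndefinedMetricError("betweenness needs at least 3 nodes")
    n = g.n_nodes
    try:  # igraph's C implementation of Brandes, identical fractional counts
        import igraph

        ig = igraph.Graph.Adjacency(g.adjacency.tolist(), mode="undirected")
        raw = np.asarray(ig.betweenness(), dtype=float)
    except ImportError:  # pragma: no cover - igraph is normally present
        bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
        raw = np.asarray([bc[i] for i in range(n)], dtype=float)
    if normalized:
        raw = raw / ((n - 1) * (n - 2) / 2.0)
    return float(raw.mean())


def modularity(
    g: BinaryGraph, seed: int = 0, n_restarts: int = 10
) -> tuple[float, list[set[int]]]:
    """Louvain community detection; best of ``n_restarts`` by Q.

    Deterministic for a fixed seed; Q = sum_c (e_cc - a_c^2).
    """
    if g.n_edges < 1:
        raise UndefinedMetricError("modularity needs at least one edge")
    G = g.to_networkx()
    best_q, best_part = -np.inf, None
    for k in range(n_restarts):
        part = nx.community.louvain_communities(G, seed=int(seed) + k)
        q = nx.community.modularity(G, part)
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


def hierarchy(g: BinaryGraph) -> float:
    """Hierarchy exponent beta: C(k) ~ k^(-beta).

    Negative slope of log clustering vs log degree over nodes with degree
    > 1 and positive clustering.  Returns NaN when fewer than two distinct
    degrees qualify (undefined-fit result).
    """
    G = g.to_networkx()
    deg = np.array([d for _, d in G.degree()], dtype=float)
    clu = np.array([nx.clustering(G, n) for n in G.nodes()], dtype=float)
    ok = (deg > 1) & (clu > 0)
    if ok.sum() < 2 or np.unique(deg[ok]).size < 2:
        return float("nan")
    fit = linregress(np.log(deg[ok]), np.log(clu[ok]))
    return float(-fit.slope)


def graph_metrics(
    conn: ConnectivityMatrix, threshold_r: float, seed: int = 0
) -> GraphMetrics:
    """The full metric battery at one threshold."""
    g = threshold_graph(conn, threshold_r)
    cpl, n_unreach = _path_length_with_count(g)
    try:
        q, _ = modularity(g, seed=seed)
    except UndefinedMetricError:
        q = float("nan")
    n_comp = nx.number_connected_components(g.to_networkx())
    return GraphMetrics(
        threshold_r=threshold_r,
        path_length=cpl,
        global_efficiency=global_efficiency(g),
        mean_degree=mean_degree(g),
        mean_betweenness=mean_betweenness(g),
        mean_betweenness_raw=mean_betweenness(g, normalized=False),
        modularity_q=q,
        hierarchy_beta=hierarchy(g),
        n_components=int(n_comp),
        n_unreachable_pairs=n_unreach,
    )


def metric_sweep(
    conn: ConnectivityMatrix,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Long-format metrics table across the threshold sweep."""
    rows = []
    for thr in thresholds:
        m = graph_metrics(conn, thr, seed=seed).to_dict()
        thr_val = m.pop("threshold_r")
        for name, value in m.items():
            rows.append((subject_id, thr_val, name, value))
    return pd.DataFrame(rows, columns=["subject_id", "threshold", "metric", "value"])
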