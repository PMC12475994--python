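"""Sparsity thresholding and graph-theoretical network metrics.

A similarity matrix is thresholded over a sparsity grid; at each threshold
the global metrics (global/local efficiency, clustering coefficient,
characteristic path length and the small-world indices gamma, lambda,
sigma) and nodal metrics (degree, efficiency, betweenness) are computed,
then summarized across the grid by the trapezoidal area under the curve.

Weighted-mode conventions: edge length = 1/weight for path-based metrics,
Onnela's form for the weighted clustering coefficient (weights normalized
by the graph maximum), and nodal degree = strength (sum of incident
weights). On a 0/1-weighted matrix every weighted metric reduces to its
binary counterpart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .exceptions import (
    DisconnectedGraphError,
    EmptyGraphError,
    RewiringError,
)

GLOBAL_METRICS = ("e_glob", "e_loc", "cp", "lp")
SMALL_WORLD_METRICS = ("gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "nodal_efficiency", "betweenness")


@dataclass
class SparsityGrid:
    """Uniform grid of sparsity thresholds (fraction of edges retained)."""

    s_min: float = 0.10
    s_max: float = 0.34
    step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min < self.s_max <= 1):
            raise ValueError("require 0 < s_min < s_max <= 1")

    @property
    def thresholds(self) -> np.ndarray:
        count = round((self.s_max - self.s_min) / self.step) + 1
        return np.linspace(self.s_min, self.s_max, count)

    @property
    def width(self) -> float:
        return self.s_max - self.s_min


@dataclass
class ThresholdedGraph:
    """Undirected graph obtained by keeping the strongest edges of a matrix."""

    adjacency: np.ndarray
    sparsity: float
    mode: str  # "weighted" | "binary"

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_list(self):
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


def round_half_up(x: float) -> int:
    # Round to 9 decimals first so exact .5 products survive float noise
    # (e.g. 0.3 * 435 = 130.49999999999997 must round as 130.5).
    return int(math.floor(round(x, 9) + 0.5))


def threshold_at_sparsity(matrix, s: float, mode: str = "weighted") -> ThresholdedGraph:
    """Retain exactly ``round_half_up(s * N(N-1)/2)`` strongest edges.

    Ties at the weight cutoff are broken by ascending (i, j) lexicographic
    order so the retained edge set is deterministic.
    """
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if not 0 < s <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if mode not in ("weighted", "binary"):
        raise ValueError(f"unknown mode: {mode!r}")
    m_possible = n * (n - 1) // 2
    n_edges = round_half_up(s * m_possible)
    if n_edges == 0:
        raise EmptyGraphError(f"sparsity {s} retains zero edges for N={n}")

    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    # lexsort: last key is primary -> strongest first, then (i, j) ascending.
    order = np.lexsort((ju, iu, -w))[:n_edges]
    adj = np.zeros_like(values)
    kept_w = 1.0 if mode == "binary" else w[order]
    adj[iu[order], ju[order]] = kept_w
    adj[ju[order], iu[order]] = kept_w
    return ThresholdedGraph(adjacency=adj, sparsity=s, mode=mode)


def nodal_degree(g: ThresholdedGraph) -> np.ndarray:
    """Binary mode: neighbor count; weighted mode: strength."""
    if g.mode == "binary":
        return (g.adjacency > 0).sum(axis=1).astype(float)
    return g.adjacency.sum(axis=1)


def clustering_coefficient(g: ThresholdedGraph):
    """Clustering coefficient; network Cp is the mean over all nodes.

    Binary: C_i = 2 t_i / (k_i (k_i - 1)). Weighted: Onnela's geometric-mean
    form with weights normalized by the graph's maximum weight. Nodes with
    fewer than 2 neighbors contribute 0.
    """
    a = g.adjacency
    k = (a > 0).sum(axis=1)
    if g.mode == "binary":
        w_hat = (a > 0).astype(float)
    else:
        w_max = a.max()
        w_hat = a / w_max if w_max > 0 else a
    w3 = np.cbrt(w_hat)
    cycles = np.diag(w3 @ w3 @ w3)  # sum over ordered (j, h) triangles at i
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, cycles / (k * (k - 1.0)), 0.0)
    return float(c.mean()), c


def _distance_matrix(adjacency: np.ndarray) -> np.ndarray:
    lengths = np.zeros_like(adjacency)
    nz = adjacency > 0
    lengths[nz] = 1.0 / adjacency[nz]
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


@dataclass
class PathEfficiency:
    lp: float
    e_glob: float
    nodal_efficiency: np.ndarray
    disconnected: bool


def path_and_efficiency(g: ThresholdedGraph) -> PathEfficiency:
    """Characteristic path length, global efficiency and nodal efficiency.

    Unreachable pairs contribute 0 to the efficiencies; Lp is averaged over
    reachable pairs only, with ``disconnected=True`` flagging that any pair
    was unreachable.
    """
    n = g.n_nodes
    d = _distance_matrix(g.adjacency)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    e_glob = inv[off].sum() / (n * (n - 1))
    nodal_eff = inv.sum(axis=1) / (n - 1)
    disconnected = bool((~finite & off).any())
    lp = float(d[finite].mean()) if finite.any() else float("inf")
    return PathEfficiency(lp=lp, e_glob=float(e_glob),
                          nodal_efficiency=nodal_eff, disconnected=disconnected)


def local_efficiency(g: ThresholdedGraph):
    """Mean global efficiency of each node's neighbor-induced subgraph.

    Edge weights are inherited from the parent graph; nodes with fewer than
    2 neighbors get 0.
    """
    a = g.adjacency
    n = g.n_nodes
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i] > 0)
        m = len(nbrs)
        if m < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = _distance_matrix(sub)
        off = ~np.eye(m, dtype=bool)
        finite = off & np.isfinite(d)
        inv = np.zeros_like(d)
        inv[finite] = 1.0 / d[finite]
        eloc[i] = inv[off].sum() / (m * (m - 1))
    return float(eloc.mean()), eloc


def _to_networkx(g: ThresholdedGraph) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(g.n_nodes))
    for i, j in g.edge_list():
        graph.add_edge(i, j, length=1.0 / g.adjacency[i, j])
    return graph


def betweenness(g: ThresholdedGraph) -> np.ndarray:
    """Shortest-path betweenness (Brandes), endpoints excluded.

    Weighted mode uses 1/weight edge lengths; equal-length path
    multiplicities are split fractionally.
    """
    graph = _to_networkx(g)
    weight = None if g.mode == "binary" else "length"
    bc = nx.betweenness_centrality(graph, weight=weight, normalized=False)
    return np.array([bc[i] for i in range(g.n_nodes)])


@dataclass
class SmallWorldResult:
    gamma: float
    lambda_: float
    sigma: float
    null_cp: np.ndarray
    null_lp: np.ndarray


def small_world_indices(
    g: ThresholdedGraph,
    n_null: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
    min_reachable: float = 0.95,
) -> SmallWorldResult:
    """Small-world indices against a degree-preserving null ensemble.

    ``n_null`` Maslov-Sneppen rewired graphs (double-edge swaps preserving
    the binary degree sequence) define the null; in weighted mode the
    multiset of edge weights is preserved and reassigned at random to the
    rewired topology. gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>,
    sigma = gamma/lambda. Deterministic given ``seed``.
    """
    pe = path_and_efficiency(g)
    n = g.n_nodes
    reachable = np.isfinite(_distance_matrix(g.adjacency))
    frac = (reachable.sum() - n) / (n * (n - 1))
    if frac < min_reachable:
        raise DisconnectedGraphError(
            f"only {frac:.1%} of node pairs reachable (need >= {min_reachable:.0%})"
        )
    cp, _ = clustering_coefficient(g)
    lp = pe.lp

    topology = _to_networkx(g)
    weights = np.array([g.adjacency[i, j] for i, j in g.edge_list()])
    n_edges = len(weights)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_null)

    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for k in range(n_null):
        h = topology.copy()
        nswap = n_swaps_per_edge * n_edges
        try:
            nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap,
                                seed=int(sub_seeds[k]))
        except nx.NetworkXError as exc:  # pragma: no cover - pathological input
            raise RewiringError(f"null graph {k}: {exc}") from exc
        adj = np.zeros((n, n))
        edges = list(h.edges())
        if g.mode == "weighted":
            w = np.random.default_rng(sub_seeds[k]).permutation(weights)
        else:
            w = np.ones(n_edges)
        for (i, j), wij in zip(edges, w):
            adj[i, j] = adj[j, i] = wij
        null = ThresholdedGraph(adjacency=adj, sparsity=g.sparsity, mode=g.mode)
        null_cp[k], _ = clustering_coefficient(null)
        null_lp[k] = path_and_efficiency(null).lp

    gamma = cp / null_cp.mean()
    lam = lp / null_lp.mean()
    return SmallWorldResult(gamma=float(gamma), lambda_=float(lam),
                            sigma=float(gamma / lam),
                            null_cp=null_cp, null_lp=null_lp)


@dataclass
class NullModelConfig:
    n_null: int = 100
    n_swaps_per_edge: int = 10
    # Minimum fraction of reachable node pairs required before computing
    # small-world indices; below it Lp is not considered representative.
    min_reachable: float = 0.95


@dataclass
class MetricCurves:
    """Per-threshold metric values plus their AUC summaries."""

    thresholds: np.ndarray
    global_curves: pd.DataFrame  # index: sparsity, columns: metric names
    nodal_curves: dict  # metric -> (n_thresholds, n_nodes) array
    auc_global: dict = field(default_factory=dict)
    auc_nodal: dict = field(default_factory=dict)
    mode: str = "weighted"
    disconnected_at: list = field(default_factory=list)
    subject_id: str = "subject"

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long format: subject, metric, node_or_global, sparsity, value."""
        rows = []
        for metric in self.global_curves.columns:
            for s, v in zip(self.thresholds, self.global_curves[metric]):
                rows.append((self.subject_id, metric, "global", s, v))
        for metric, arr in self.nodal_curves.items():
            for t_idx, s in enumerate(self.thresholds):
                for node in range(arr.shape[1]):
                    rows.append((self.subject_id, metric, node, s, arr[t_idx, node]))
        return pd.DataFrame(
            rows, columns=["subject", "metric", "node_or_global", "sparsity", "value"]
        )

    def auc_frame(self) -> pd.DataFrame:
        rows = [(self.subject_id, m, "global", v) for m, v in self.auc_global.items()]
        for metric, arr in self.auc_nodal.items():
            rows.extend(
                (self.subject_id, metric, node, arr[node]) for node in range(len(arr))
            )
        return pd.DataFrame(
            rows, columns=["subject", "metric", "node_or_global", "auc"]
        )


def metric_curves(
    matrix,
    grid: SparsityGrid = None,
    mode: str = "weighted",
    null_config: NullModelConfig = None,
    seed: int = 0,
    global_metrics=GLOBAL_METRICS,
    nodal_metrics=NODAL_METRICS,
    subject_id: str = None,
) -> MetricCurves:
    """Evaluate the requested metrics at every sparsity threshold.

    Small-world indices (gamma, lambda, sigma) are computed only when
    ``null_config`` is provided. AUCs are trapezoidal integrals over the
    sparsity grid.
    """
    grid = grid or SparsityGrid()
    thresholds = grid.thresholds
    n_t = len(thresholds)
    if subject_id is None:
        subject_id = getattr(matrix, "subject_id", "subject")

    global_metrics = list(global_metrics)
    if null_config is not None:
        global_metrics += list(SMALL_WORLD_METRICS)
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    n = values.shape[0]

    gcurves = {m: np.full(n_t, np.nan) for m in global_metrics}
    ncurves = {m: np.zeros((n_t, n)) for m in nodal_metrics}
    disconnected_at = []
    rng = np.random.default_rng(seed)
    sw_seeds = rng.integers(0, 2**31 - 1, size=n_t)

    for t_idx, s in enumerate(thresholds):
        try:
            g = threshold_at_sparsity(values, float(s), mode=mode)
        except EmptyGraphError as exc:
            raise EmptyGraphError(f"at sparsity {s:.3f}: {exc}") from exc

        need_paths = bool(
            {"e_glob", "lp", "lambda", "sigma"} & set(global_metrics)
        ) or "nodal_efficiency" in nodal_metrics
        pe = path_and_efficiency(g) if need_paths else None
        if pe is not None and pe.disconnected:
            disconnected_at.append(float(s))

        if "cp" in gcurves or null_config is not None:
            cp, _ = clustering_coefficient(g)
            if "cp" in gcurves:
                gcurves["cp"][t_idx] = cp
        if "e_glob" in gcurves:
            gcurves["e_glob"][t_idx] = pe.e_glob
        if "lp" in gcurves:
            gcurves["lp"][t_idx] = pe.lp
        if "e_loc" in gcurves:
            gcurves["e_loc"][t_idx], _ = local_efficiency(g)
        if null_config is not None:
            try:
                sw = small_world_indices(
                    g, n_null=null_config.n_null,
                    n_swaps_per_edge=null_config.n_swaps_per_edge,
                    seed=int(sw_seeds[t_idx]),
                    min_reachable=null_config.min_reachable,
                )
            except (DisconnectedGraphError, RewiringError) as exc:
                raise type(exc)(f"at sparsity {s:.3f}: {exc}") from exc
            gcurves["gamma"][t_idx] = sw.gamma
            gcurves["lambda"][t_idx] = sw.lambda_
            gcurves["sigma"][t_idx] = sw.sigma

        if "degree" in ncurves:
            ncurves["degree"][t_idx] = nodal_degree(g)
        if "nodal_efficiency" in ncurves:
            ncurves["nodal_efficiency"][t_idx] = pe.nodal_efficiency
        if "betweenness" in ncurves:
            ncurves["betweenness"][t_idx] = betweenness(g)

    gframe = pd.DataFrame(gcurves, index=pd.Index(thresholds, name="sparsity"))
    auc_global = {
        m: float(np.trapezoid(gframe[m].to_numpy(), thresholds))
        for m in gframe.columns
    }
    auc_nodal = {
        m: np.trapezoid(arr, thresholds, axis=0) for m, arr in ncurves.items()
    }
    return MetricCurves(
        thresholds=thresholds,
        global_curves=gframe,
        nodal_curves=ncurves,
        auc_global=auc_global,
        auc_nodal=auc_nodal,
        mode=mode,
        disconnected_at=disconnected_at,
        subject_id=subject_id,
    )
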