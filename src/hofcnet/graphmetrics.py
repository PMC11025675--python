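"""Sparsity thresholding and graph-theoretic network metrics.

Connectivity matrices are binarised by retaining a fixed fraction (the
sparsity S) of the strongest edges, metrics are computed on the binary
graph across a grid of sparsities (default 0.06-0.40 in steps of 0.01),
small-world coefficients are normalised against degree-preserving rewired
null networks, and each metric's profile over the grid is summarised by
its trapezoidal area under the curve (AUC).

Binary definitions are used throughout this module; the weighted local
clustering coefficient used as a classification feature lives in
:mod:`hofcnet.classify`.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

#: Default sparsity grid: 35 thresholds from 0.06 to 0.40 in steps of 0.01.
DEFAULT_SPARSITY_GRID = tuple(np.round(np.arange(6, 41) / 100.0, 2))


@dataclass
class ThresholdedGraph:
    adjacency: np.ndarray          # P x P, 0/1, symmetric, zero diagonal
    weights: np.ndarray            # original values on retained edges, else 0
    sparsity: float
    achieved_sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    eglob: float
    eloc: float


@dataclass
class SmallWorldResult:
    gamma: float
    lambda_: float
    sigma: float
    cp_rand: float
    lp_rand: float
    n_nulls: int


@dataclass
class NodalMetrics:
    bc: np.ndarray
    dc: np.ndarray
    ne: np.ndarray


def threshold_by_sparsity(m: ConnectivityMatrix | np.ndarray, sparsity: float,
                          edge_sign: str = "positive") -> ThresholdedGraph:
    """Keep the ``floor(S * P(P-1)/2)`` strongest edges of the matrix.

    ``edge_sign="positive"`` ranks (and admits) positive values only, the
    standard convention for correlation networks; ``"absolute"`` ranks by
    magnitude.  Ties at the cutoff are broken by value and then by
    lexicographic edge index, so the edge set is deterministic.
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    if edge_sign not in ("positive", "absolute"):
        raise ValueError(f"edge_sign must be 'positive' or 'absolute'")
    p = values.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    v = values[iu, ju]
    strength = np.abs(v) if edge_sign == "absolute" else v
    n_possible = p * (p - 1) // 2
    n_target = int(np.floor(sparsity * n_possible))
    eligible = np.flatnonzero(strength > 0) if edge_sign == "positive" \
        else np.arange(v.size)
    if eligible.size < n_target:
        logger.warning(
            "only %d positive edges available for target %d; achieved "
            "sparsity %.4f", eligible.size, n_target, eligible.size / n_possible)
    # sort by (-strength, i, j): deterministic under ties
    order = np.lexsort((ju[eligible], iu[eligible], -strength[eligible]))
    keep = eligible[order[:n_target]]
    adj = np.zeros((p, p))
    adj[iu[keep], ju[keep]] = 1.0
    adj += adj.T
    weights = np.where(adj > 0, values, 0.0)
    return ThresholdedGraph(adjacency=adj, weights=weights, sparsity=sparsity,
                            achieved_sparsity=keep.size / n_possible)


def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(adj), method="D", unweighted=True)


def _local_clustering(adj: np.ndarray) -> np.ndarray:
    """Binary local clustering coefficient per node (0 when degree < 2)."""
    k = adj.sum(axis=1)
    triangles = np.diag(adj @ adj @ adj)  # 2 * triangles per node
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_metrics(g: ThresholdedGraph) -> GlobalMetrics:
    """Binary Cp, Lp, Eglob, Eloc.

    Lp averages shortest-path length over *connected* ordered pairs only
    (the disconnected fraction is logged); Eglob averages 1/d over all
    ordered pairs with disconnected pairs contributing 0, so it degrades
    gracefully on fragmented graphs.
    """
    adj = g.adjacency
    n = g.n_nodes
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    cp = float(_local_clustering(adj).mean())

    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disconnected = int(off.sum() - finite.sum())
    if n_disconnected:
        logger.debug("Lp over connected pairs only; %d of %d ordered pairs "
                     "disconnected", n_disconnected, int(off.sum()))
    lp = float(d[finite].mean())
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eglob = float(inv.sum() / (n * (n - 1)))

    eloc_terms = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size >= 2:
            eloc_terms[i] = _global_efficiency(adj[np.ix_(nb, nb)])
    eloc = float(eloc_terms.mean())
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, eloc=eloc)


def rewired_nulls(g: ThresholdedGraph, n_nulls: int, seed,
                  swaps_per_edge: int = 10) -> list:
    """Degree-preserving null ensemble by repeated double-edge swaps."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = seed if isinstance(seed, random.Random) else random.Random(int(seed))
    nulls = []
    nswap = swaps_per_edge * g.n_edges
    for _ in range(n_nulls):
        gx = g.to_networkx()
        try:
            nx.double_edge_swap(gx, nswap=nswap, max_tries=100 * nswap,
                                seed=rng.randrange(2**31))
        except nx.NetworkXAlgorithmError:
            logger.warning("double-edge swap hit max_tries; null kept as-is")
        adj = nx.to_numpy_array(gx, nodelist=range(g.n_nodes))
        nulls.append(ThresholdedGraph(adjacency=adj, weights=adj.copy(),
                                      sparsity=g.sparsity,
                                      achieved_sparsity=g.achieved_sparsity))
    return nulls


def small_world(g: ThresholdedGraph, nulls) -> SmallWorldResult:
    """Normalised clustering (gamma), path length (lambda) and sigma.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma/lambda.
    """
    if not nulls:
        raise ValueError("null ensemble is empty")
    gm = global_metrics(g)
    null_metrics = [global_metrics(h) for h in nulls]
    cp_rand = float(np.mean([m.cp for m in null_metrics]))
    lp_rand = float(np.mean([m.lp for m in null_metrics]))
    if cp_rand == 0:
        logger.warning("null ensemble mean clustering is 0; gamma undefined")
        gamma = np.nan
    else:
        gamma = gm.cp / cp_rand
    lambda_ = gm.lp / lp_rand
    return SmallWorldResult(gamma=gamma, lambda_=lambda_, sigma=gamma / lambda_,
                            cp_rand=cp_rand, lp_rand=lp_rand, n_nulls=len(nulls))


def nodal_metrics(g: ThresholdedGraph) -> NodalMetrics:
    """Betweenness centrality, degree, nodal efficiency per node.

    Bc is the unnormalised shortest-path betweenness (fractional credit
    for tied geodesics); Ne(i) is the mean of 1/d(i, j) over j != i with
    disconnected pairs contributing 0.
    """
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    n = g.n_nodes
    bc_dict = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    bc = np.array([bc_dict[i] for i in range(n)])
    dc = g.degrees().astype(float)
    d = _distances(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(bc=bc, dc=dc, ne=ne)


def auc_over_sparsity(values, grid) -> float:
    """Trapezoidal area under a metric's sparsity profile."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("need at least 2 sparsity points for an AUC")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    if values.shape != grid.shape:
        raise ValueError(f"{values.size} values for {grid.size} grid points")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"missing metric value at sparsity "
                         f"{grid[bad[0]]:.2f}")
    return float(np.trapezoid(values, grid))


@dataclass
class MetricTable:
    """Per-subject, per-sparsity metrics plus AUC summaries (long format)."""

    rows: list = field(default_factory=list)

    def add(self, subject_id, network_kind, sparsity, metric, node, value):
        self.rows.append({"subject": subject_id, "network_kind": network_kind,
                          "sparsity": sparsity, "metric": metric,
                          "node_or_global": node, "value": value})

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


def metrics_over_grid(m: ConnectivityMatrix, grid=DEFAULT_SPARSITY_GRID,
                      n_nulls: int = 0, seed: int = 0,
                      edge_sign: str = "positive") -> dict:
    """Global (and optionally small-world) metrics at every grid sparsity.

    Returns a dict with per-sparsity GlobalMetrics / NodalMetrics lists and
    AUC summaries of the global metrics.  ``n_nulls=0`` skips the (costly)
    rewired-null normalisation.
    """
    grid = np.asarray(grid, dtype=float)
    per_global, per_nodal, per_sw = [], [], []
    for s_idx, s in enumerate(grid):
        g = threshold_by_sparsity(m, float(s), edge_sign=edge_sign)
        per_global.append(global_metrics(g))
        per_nodal.append(nodal_metrics(g))
        if n_nulls > 0:
            nulls = rewired_nulls(g, n_nulls, seed=seed * 100003 + s_idx)
            per_sw.append(small_world(g, nulls))
    auc = {name: auc_over_sparsity([getattr(gm, name) for gm in per_global], grid)
           for name in ("cp", "lp", "eglob", "eloc")}
    if per_sw:
        for name in ("gamma", "lambda_", "sigma"):
            vals = [getattr(sw, name) for sw in per_sw]
            if np.all(np.isfinite(vals)):
                auc[name] = auc_over_sparsity(vals, grid)
            else:
                logger.warning("%s undefined at some sparsities; AUC skipped",
                               name)
    return {"grid": grid, "global": per_global, "nodal": per_nodal,
            "small_world": per_sw, "auc": auc}
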