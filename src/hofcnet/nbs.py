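"""Network-based statistic (NBS).

Edgewise covariate-adjusted two-sample contrasts are thresholded at a
primary uncorrected p value; the surviving edges form a graph whose
connected components are scored by edge count against a permutation null
distribution of the *maximal* component size, which controls the
family-wise error rate at the component level.  Group labels are permuted
with each subject's covariates kept attached to the subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from ._ols import group_t
from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

TAILS = ("patient_gt", "control_gt", "both")


@dataclass
class NbsConfig:
    primary_p: float = 0.001
    n_perm: int = 1000
    alpha: float = 0.01
    seed: int = 0
    tail: str = "both"

    def __post_init__(self) -> None:
        if not 0 < self.primary_p < 1:
            raise ValueError("primary_p must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")


@dataclass
class Component:
    edges: list            # (i, j) with i < j
    nodes: list
    size: int              # edge count
    corrected_p: float | None = None


@dataclass
class NbsResult:
    t_matrix: np.ndarray
    p_matrix: np.ndarray
    components: list
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    config: NbsConfig | None = None

    @property
    def significant(self) -> list:
        alpha = self.config.alpha if self.config else 0.05
        return [c for c in self.components
                if c.corrected_p is not None and c.corrected_p < alpha]


def _stack_edges(matrices):
    mats = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
            for m in matrices]
    p = mats[0].shape[0]
    iu, ju = np.triu_indices(p, k=1)
    y = np.stack([m[iu, ju] for m in mats])
    return y, p, iu, ju


def _unstack(vec, p, iu, ju, fill=0.0):
    out = np.full((p, p), fill)
    out[iu, ju] = vec
    out[ju, iu] = vec
    np.fill_diagonal(out, 0.0)
    return out


def edgewise_stats(matrices, groups, covariates=None):
    """Per-edge group t and two-sided p matrices (covariate-adjusted)."""
    groups = np.asarray(groups, dtype=bool)
    for label, count in (("patient", groups.sum()), ("control", (~groups).sum())):
        if count < 2:
            raise ValueError(f"need at least 2 {label} subjects")
    y, p, iu, ju = _stack_edges(matrices)
    t, pv, _ = group_t(y, groups, covariates)
    n_degen = int(np.sum(~np.isfinite(t)) + np.sum(np.isinf(t)))
    if n_degen:
        logger.warning("%d edges with zero residual variance", n_degen)
    return _unstack(t, p, iu, ju), _unstack(pv, p, iu, ju, fill=1.0)


def _suprathreshold_mask(t, pv, primary_p, tail):
    mask = pv < primary_p
    if tail == "patient_gt":
        mask &= t > 0
    elif tail == "control_gt":
        mask &= t < 0
    return mask


def extract_components(p_matrix, t_matrix, primary_p=0.001, tail="both"):
    """Connected components of the suprathreshold-edge graph.

    Component ``size`` is the number of edges; the list is sorted by size,
    largest first.  An empty list is a legitimate result.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    p = p_matrix.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    mask = _suprathreshold_mask(t_matrix[iu, ju], p_matrix[iu, ju],
                                primary_p, tail)
    if not mask.any():
        return []
    adj = np.zeros((p, p))
    adj[iu[mask], ju[mask]] = 1.0
    adj += adj.T
    n_comp, labels = connected_components(csr_array(adj), directed=False)
    comps = []
    for c in range(n_comp):
        nodes = np.flatnonzero(labels == c)
        if nodes.size < 2:
            continue
        node_set = set(nodes.tolist())
        edges = [(int(i), int(j)) for i, j in zip(iu[mask], ju[mask])
                 if int(i) in node_set]
        if not edges:
            continue
        comps.append(Component(edges=edges, nodes=sorted(node_set),
                               size=len(edges)))
    comps.sort(key=lambda c: -c.size)
    return comps


def _max_component_size(t, pv, primary_p, tail, p, iu, ju):
    mask = _suprathreshold_mask(t, pv, primary_p, tail)
    if not mask.any():
        return 0
    adj = np.zeros((p, p))
    adj[iu[mask], ju[mask]] = 1.0
    adj += adj.T
    _, labels = connected_components(csr_array(adj), directed=False)
    edge_labels = labels[iu[mask]]
    return int(np.bincount(edge_labels).max())


def nbs_test(matrices, groups, covariates=None,
             config: NbsConfig | None = None) -> NbsResult:
    """Full NBS: observed components scored against the permutation null.

    Corrected p values use +1 smoothing:
    ``(1 + #{null max size >= observed size}) / (1 + n_perm)``.
    """
    config = config or NbsConfig()
    groups = np.asarray(groups, dtype=bool)
    y, p, iu, ju = _stack_edges(matrices)
    t_obs, p_obs, _ = group_t(y, groups, covariates)
    t_mat = _unstack(t_obs, p, iu, ju)
    p_mat = _unstack(p_obs, p, iu, ju, fill=1.0)
    comps = extract_components(p_mat, t_mat, config.primary_p, config.tail)

    rng = np.random.default_rng(config.seed)
    null_max = np.empty(config.n_perm, dtype=int)
    for b in range(config.n_perm):
        perm = rng.permutation(groups)
        t_b, p_b, _ = group_t(y, perm, covariates)
        null_max[b] = _max_component_size(t_b, p_b, config.primary_p,
                                          config.tail, p, iu, ju)
    for c in comps:
        c.corrected_p = float((1 + np.sum(null_max >= c.size))
                              / (1 + config.n_perm))
    return NbsResult(t_matrix=t_mat, p_matrix=p_mat, components=comps,
                     null_max_sizes=null_max, config=config)
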