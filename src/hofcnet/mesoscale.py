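"""Modular architecture and rich-club organisation.

The parcellation carries a fixed five-module partition (sensorimotor,
default-mode, fronto-parietal, visual, subcortical).  Modular segregation
is summarised by mean intra- and inter-module connection strength on the
weighted (unthresholded) matrix.  Rich-club nodes are the ten regions with
the highest binary degree of the group-averaged network, averaged over the
sparsity grid; edges are then classified as rich (both endpoints rich),
feeder (one endpoint rich) or local (neither).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .graphmetrics import DEFAULT_SPARSITY_GRID, ThresholdedGraph, threshold_by_sparsity

logger = logging.getLogger(__name__)

RICH_CLUB_SIZE = 10
EDGE_CLASSES = ("rich", "feeder", "local")


@dataclass
class ModularStrengths:
    intra: dict     # module -> mean weight (None when undefined)
    inter: dict     # frozenset({a, b}) -> mean weight


@dataclass
class RichClubResult:
    rich_nodes: list                 # region indices, sorted
    edge_class: dict                 # (i, j) i<j -> class name
    mean_strength: dict              # class -> mean original weight (or None)
    class_counts: dict


def _values_and_labels(m):
    if isinstance(m, ConnectivityMatrix):
        return m.values, m.region_labels
    return np.asarray(m), None


def modular_strengths(m, partition, region_labels=None) -> ModularStrengths:
    """Mean weighted connection strength within and between modules.

    ``partition`` maps region label -> module.  Means run over every
    distinct region pair of the block; single-region modules have no
    within-module pair and report ``None``.
    """
    values, labels = _values_and_labels(m)
    labels = region_labels if region_labels is not None else labels
    if labels is None:
        labels = [str(i) for i in range(values.shape[0])]
    missing = [r for r in labels if r not in partition]
    if missing:
        raise ValueError(f"partition does not cover regions: {missing}")
    modules = sorted({partition[r] for r in labels})
    members = {mod: np.array([i for i, r in enumerate(labels)
                              if partition[r] == mod]) for mod in modules}
    intra, inter = {}, {}
    for mod in modules:
        idx = members[mod]
        if idx.size < 2:
            logger.warning("module %s has a single region; intra-module "
                           "strength undefined", mod)
            intra[mod] = None
            continue
        block = values[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        intra[mod] = float(block[iu].mean())
    for a_i, mod_a in enumerate(modules):
        for mod_b in modules[a_i + 1:]:
            block = values[np.ix_(members[mod_a], members[mod_b])]
            inter[frozenset((mod_a, mod_b))] = float(block.mean())
    return ModularStrengths(intra=intra, inter=inter)


def rich_club_nodes(group_matrices, grid=DEFAULT_SPARSITY_GRID,
                    n_rich: int = RICH_CLUB_SIZE, method: str = "degree",
                    edge_sign: str = "positive") -> list:
    """Top-degree nodes of the group-averaged network.

    The subject matrices are averaged entrywise; the mean network is
    thresholded at each grid sparsity and each node's binary degree is
    averaged across the grid (``method="degree"``).  ``method="strength"``
    ranks by weighted nodal strength of the unthresholded mean matrix
    instead.  Ties are broken by (mean degree, then region index) and
    logged.
    """
    mats = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
            for m in group_matrices]
    if not mats:
        raise ValueError("need at least one subject matrix")
    p = mats[0].shape[0]
    if p < n_rich:
        raise ValueError(f"cannot pick {n_rich} rich nodes from {p} regions")
    mean_net = np.mean(mats, axis=0)
    if method == "strength":
        score = np.where(mean_net > 0, mean_net, 0.0).sum(axis=1)
    elif method == "degree":
        degs = np.zeros(p)
        for s in grid:
            g = threshold_by_sparsity(mean_net, float(s), edge_sign=edge_sign)
            degs += g.degrees()
        score = degs / len(grid)
    else:
        raise ValueError(f"unknown rich-club method {method!r}")
    # descending score, ascending index on ties
    order = np.lexsort((np.arange(p), -score))
    cutoff = score[order[n_rich - 1]]
    n_tied = int(np.sum(score == cutoff))
    if n_tied > 1 and np.sum(score > cutoff) < n_rich:
        logger.info("rich-club cutoff score %.4f shared by %d nodes; tie "
                    "broken by region index", cutoff, n_tied)
    return sorted(int(i) for i in order[:n_rich])


def classify_connections(g: ThresholdedGraph, rich_nodes) -> RichClubResult:
    """Label every edge rich / feeder / local by endpoint membership."""
    rich = set(int(i) for i in rich_nodes)
    unknown = rich - set(range(g.n_nodes))
    if unknown:
        raise ValueError(f"rich nodes outside graph: {sorted(unknown)}")
    iu, ju = np.triu_indices(g.n_nodes, k=1)
    present = g.adjacency[iu, ju] > 0
    edge_class, strengths = {}, {c: [] for c in EDGE_CLASSES}
    for i, j in zip(iu[present], ju[present]):
        n_rich_ends = (int(i) in rich) + (int(j) in rich)
        cls = ("local", "feeder", "rich")[n_rich_ends]
        edge_class[(int(i), int(j))] = cls
        strengths[cls].append(g.weights[i, j])
    mean_strength = {}
    for cls in EDGE_CLASSES:
        if strengths[cls]:
            mean_strength[cls] = float(np.mean(strengths[cls]))
        else:
            logger.warning("no %s connections in this graph", cls)
            mean_strength[cls] = None
    counts = {c: sum(v == c for v in edge_class.values()) for c in EDGE_CLASSES}
    return RichClubResult(rich_nodes=sorted(rich), edge_class=edge_class,
                          mean_strength=mean_strength, class_counts=counts)
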