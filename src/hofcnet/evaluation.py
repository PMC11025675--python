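"""Desk-scale calibration and recovery experiments on synthetic cohorts.

These routines exercise the full pipeline under the study conditions the
synthetic generator emulates and measure what the method should deliver
there: family-wise error control and power of the network-based statistic,
small-world normalisation behaviour on canonical graph families, chance
and separable-case classifier behaviour, and sign recovery of planted
modular effects.  Problem sizes are chosen so each experiment runs in
minutes on one core while keeping the cohort dimensions of the emulated
study (60 patients / 50 controls, 90 regions) where they matter.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from . import synthio
from .classify import ClassifierConfig, nested_loocv_classify
from .connectivity import fisher_z, lofc_matrix
from .graphmetrics import ThresholdedGraph, rewired_nulls, small_world
from .mesoscale import modular_strengths
from .nbs import NbsConfig, nbs_test

MODULE_SIZES_90 = dict(synthio.DEFAULT_MODULE_SIZES)


def _graph_from_nx(gx: nx.Graph, n: int) -> ThresholdedGraph:
    adj = nx.to_numpy_array(gx, nodelist=range(n))
    m = int(adj.sum()) // 2
    s = m / (n * (n - 1) / 2)
    return ThresholdedGraph(adjacency=adj, weights=adj.copy(), sparsity=s,
                            achieved_sparsity=s)


def smallworld_er_calibration(n_nodes: int = 90, sparsity: float = 0.2,
                              n_nulls: int = 20, seed: int = 0) -> dict:
    """gamma/lambda of an Erdos-Renyi graph against its rewired nulls.

    An ER graph is (asymptotically) its own degree-randomised null family,
    so both normalised coefficients should sit near 1.
    """
    n_edges = int(np.floor(sparsity * n_nodes * (n_nodes - 1) / 2))
    gx = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    g = _graph_from_nx(gx, n_nodes)
    sw = small_world(g, rewired_nulls(g, n_nulls, seed=seed + 1))
    return {"gamma": sw.gamma, "lambda": sw.lambda_, "sigma": sw.sigma}


def smallworld_ws_sigma(n_nodes: int = 90, k: int = 10,
                        p_rewire: float = 0.1, n_nulls: int = 20,
                        seed: int = 0) -> float:
    """Small-worldness of a Watts-Strogatz graph (canonical sigma > 1 case)."""
    gx = nx.watts_strogatz_graph(n_nodes, k, p_rewire, seed=seed)
    g = _graph_from_nx(gx, n_nodes)
    return small_world(g, rewired_nulls(g, n_nulls, seed=seed + 1)).sigma


def _subject_z_matrices(cov_patient, cov_control, n_per_group, t_len, rng):
    mats, groups = [], []
    for cov, is_pat in ((cov_patient, True), (cov_control, False)):
        for _ in range(n_per_group):
            ts = synthio.sample_timeseries(cov, t_len, ar_coef=0.0, seed=rng)
            mats.append(fisher_z(lofc_matrix(ts)).values)
            groups.append(is_pat)
    return mats, np.array(groups, dtype=bool)


def nbs_fwe_calibration(n_runs: int = 40, n_per_group: int = 30,
                        n_regions: int = 90, t_len: int = 120,
                        n_perm: int = 200, alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Empirical family-wise error rate of the NBS under the global null.

    Both groups are drawn from the same connectivity structure; a run
    counts as a false positive when any component reaches corrected
    p < ``alpha``.  Returns the fraction of such runs.
    """
    cfg = synthio.GeneratorConfig(n_regions=n_regions, effects=(),
                                  module_sizes=_sizes_for(n_regions))
    cov = synthio.build_group_covariance(cfg, "control")
    rng = np.random.default_rng(seed)
    false_positives = 0
    for run in range(n_runs):
        mats, groups = _subject_z_matrices(cov, cov, n_per_group, t_len, rng)
        res = nbs_test(mats, groups,
                       config=NbsConfig(n_perm=n_perm, seed=seed + 7919 * run))
        if any(c.corrected_p < alpha for c in res.components):
            false_positives += 1
    return false_positives / n_runs


#: 10-edge connected subnetwork planted for the NBS power experiment.
PLANTED_EDGES = ((0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (3, 5),
                 (5, 6), (6, 7), (7, 8))


def nbs_recovery(n_seeds: int = 20, delta: float = 0.25,
                 n_per_group: int = 30, n_regions: int = 90,
                 t_len: int = 120, n_perm: int = 200,
                 alpha: float = 0.05, seed: int = 0) -> float:
    """Power of the NBS to recover a planted 10-edge subnetwork.

    Patients get ``delta`` added to the correlation of the planted edges.
    A seed counts as a recovery when a significant component overlaps the
    planted edge set with Jaccard index >= 0.5.  Returns the recovery rate.
    """
    base = np.full((n_regions, n_regions), 0.1)
    np.fill_diagonal(base, 1.0)
    cov_control, _ = synthio.nearest_positive_definite(base)
    planted = base.copy()
    for i, j in PLANTED_EDGES:
        planted[i, j] = planted[j, i] = 0.1 + delta
    cov_patient, _ = synthio.nearest_positive_definite(planted)
    planted_set = {tuple(sorted(e)) for e in PLANTED_EDGES}
    recovered = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 104729 * s)
        mats, groups = _subject_z_matrices(cov_patient, cov_control,
                                           n_per_group, t_len, rng)
        res = nbs_test(mats, groups,
                       config=NbsConfig(n_perm=n_perm, seed=seed + s))
        for c in res.components:
            if c.corrected_p >= alpha:
                continue
            found = {tuple(sorted(e)) for e in c.edges}
            jac = len(found & planted_set) / len(found | planted_set)
            if jac >= 0.5:
                recovered += 1
                break
    return recovered / n_seeds


def modular_effect_recovery(n_seeds: int = 20, delta: float = 0.12,
                            n_patient: int = 60, n_control: int = 50,
                            t_len: int = 239, seed: int = 0) -> float:
    """Sign recovery of the planted SMN-DMN inter-module increase.

    For each seed a full default-size cohort is generated (patients carry
    +``delta`` on the SMN-DMN block), per-subject LOFC modular strengths
    are computed, and the patient-minus-control difference of the mean
    SMN-DMN inter strength is checked for the planted (positive) sign.
    Returns the fraction of seeds with the correct sign.
    """
    correct = 0
    for s in range(n_seeds):
        cfg = synthio.GeneratorConfig(
            n_patient=n_patient, n_control=n_control,
            n_timepoints=t_len, seed=seed + 15485863 * s,
            effects=(("SMN", "DMN", delta, "patient"),))
        ds = synthio.generate_cohort(cfg)
        key = frozenset(("SMN", "DMN"))
        diffs = {"patient": [], "control": []}
        for subj in ds.subjects:
            m = lofc_matrix(subj.timeseries, ds.region_labels)
            ms = modular_strengths(m, ds.partition)
            diffs[subj.group].append(ms.inter[key])
        if np.mean(diffs["patient"]) - np.mean(diffs["control"]) > 0:
            correct += 1
    return correct / n_seeds


def classifier_separable_accuracy(n_per_class: int = 10, n_features: int = 90,
                                  separation: float = 3.0,
                                  seed: int = 0) -> float:
    """LOOCV accuracy on two well-separated spherical clusters (expect 100)."""
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(separation, 1.0, (n_per_class, n_features)),
                   rng.normal(-separation, 1.0, (n_per_class, n_features))])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return nested_loocv_classify(x, y, ClassifierConfig(seed=seed)).acc


def classifier_chance_level(n_repeats: int = 20, n_pos: int = 60,
                            n_neg: int = 50, n_features: int = 90,
                            seed: int = 0) -> float:
    """Mean LOOCV accuracy with permuted labels (expect the majority rate).

    Features carry no class signal, so the nested pipeline should hover
    near the majority-class rate (54.5% at 60/50); a systematic excess
    would indicate information leaking across the fold boundary.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_pos + n_neg, n_features))
    y = np.array([1] * n_pos + [0] * n_neg)
    accs = []
    for rep in range(n_repeats):
        res = nested_loocv_classify(x, rng.permutation(y),
                                    ClassifierConfig(seed=seed + rep))
        accs.append(res.acc)
    return float(np.mean(accs))


def _sizes_for(n_regions: int) -> dict:
    if n_regions == 90:
        return dict(MODULE_SIZES_90)
    base = n_regions // 5
    sizes = {m: base for m in synthio.MODULE_NAMES}
    sizes["SN"] += n_regions - 5 * base
    return sizes
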