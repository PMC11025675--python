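"""Covariate-adjusted group comparisons of derived scalar measures.

Each measure (a metric AUC, a nodal value, a modular or edge-class
strength) is compared between groups by a least-squares contrast
adjusting for age, gender and education; nodal families are Bonferroni
corrected; non-normal measures can be routed to a label-permutation test
instead (Shapiro-Wilk screening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._ols import group_t

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    measure: str
    t_stat: float | None
    p_raw: float
    p_adjusted: float | None
    adjust_method: str          # bonferroni | permutation | none
    direction: int              # sign of (patient - control), adjusted


def _direction(values, groups, covariates):
    """Sign of the adjusted patient-control difference (group coefficient)."""
    t, _, _ = group_t(values, groups, covariates)
    return int(np.sign(t)) if np.isfinite(t) else 0


def adjusted_two_sample_test(values, groups, covariates=None,
                             measure: str = "measure") -> ComparisonResult:
    """Group contrast of one scalar measure, adjusted for covariates."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    if min(groups.sum(), (~groups).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.ptp(values) == 0:
        logger.warning("measure %s is constant; comparison undefined", measure)
        return ComparisonResult(measure, None, np.nan, None, "none", 0)
    t, p, _ = group_t(values, groups, covariates)
    return ComparisonResult(measure=measure, t_stat=t, p_raw=p,
                            p_adjusted=None, adjust_method="none",
                            direction=int(np.sign(t)))


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """p * m capped at 1; family size defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, p * m)


def permutation_compare(values, groups, covariates=None, n_perm: int = 1000,
                        seed: int = 0, measure: str = "measure"
                        ) -> ComparisonResult:
    """Two-sided label-permutation test of the adjusted group contrast.

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm); covariates stay
    attached to their subjects when labels are permuted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    if np.ptp(values) == 0:
        logger.warning("measure %s is constant; comparison undefined", measure)
        return ComparisonResult(measure, None, np.nan, None, "permutation", 0)
    t_obs, _, _ = group_t(values, groups, covariates)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        t_b, _, _ = group_t(values, rng.permutation(groups), covariates)
        if abs(t_b) >= abs(t_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ComparisonResult(measure=measure, t_stat=t_obs, p_raw=p,
                            p_adjusted=p, adjust_method="permutation",
                            direction=int(np.sign(t_obs)))


def route_by_normality(values, groups, alpha: float = 0.05) -> str:
    """'ttest' when both group distributions pass Shapiro-Wilk, else
    'permutation'.  The routing is logged and can be overridden by calling
    the desired test directly."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    for g in (groups, ~groups):
        sample = values[g]
        if sample.size < 3 or np.ptp(sample) == 0:
            logger.info("normality screen inconclusive; routing to permutation")
            return "permutation"
        if stats.shapiro(sample).pvalue < alpha:
            logger.info("normality rejected (Shapiro-Wilk p < %g); routing "
                        "to permutation", alpha)
            return "permutation"
    return "ttest"


def compare_measures(measure_matrix, measure_names, groups, covariates=None,
                     bonferroni_family: int | None = None) -> list:
    """Adjusted comparisons of many measures with Bonferroni correction.

    ``measure_matrix`` is (n_subjects, n_measures); the Bonferroni family
    defaults to the number of measures (e.g. 90 for a nodal family).
    """
    measure_matrix = np.asarray(measure_matrix, dtype=float)
    results = [adjusted_two_sample_test(measure_matrix[:, j], groups,
                                        covariates, measure=name)
               for j, name in enumerate(measure_names)]
    valid = [r for r in results if r.t_stat is not None]
    if valid:
        m = bonferroni_family if bonferroni_family is not None else len(valid)
        adjusted = bonferroni_adjust([r.p_raw for r in valid], m)
        for r, pa in zip(valid, adjusted):
            r.p_adjusted = float(pa)
            r.adjust_method = "bonferroni"
    return results
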