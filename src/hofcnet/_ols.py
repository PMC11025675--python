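"""Shared covariate-adjusted group-contrast least squares.

Both the edgewise network-based statistic and the scalar group
comparisons fit, per outcome, value ~ intercept + group + covariates and
report the t statistic of the group indicator.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def group_design(groups: np.ndarray, covariates: np.ndarray | None):
    """Design matrix [1, group, covariates]; group coded patient=1."""
    g = np.asarray(groups, dtype=float).reshape(-1)
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def group_t(y: np.ndarray, groups: np.ndarray,
            covariates: np.ndarray | None = None):
    """t and two-sided p for the group coefficient, per column of ``y``.

    ``y`` may be a vector (one outcome) or an (n, m) matrix (m outcomes,
    fitted simultaneously).  Rank deficiency is handled by the SVD
    pseudo-inverse; the degrees of freedom use the design's actual rank.
    Outcomes with zero residual variance get p = 0 when the group effect
    is nonzero (the groups are perfectly separated) and p = 1 otherwise.
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    x = group_design(groups, covariates)
    n, k = x.shape
    rank = np.linalg.matrix_rank(x)
    dof = n - rank
    if dof <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, rank={rank})")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    var_g = (pinv @ pinv.T)[1, 1]  # variance factor of the group coefficient
    se = np.sqrt(sigma2 * var_g)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = se == 0
    if degenerate.any():
        t = np.where(degenerate, np.sign(beta[1]) * np.inf, t)
        p = np.where(degenerate, np.where(beta[1] == 0, 1.0, 0.0), p)
        t = np.where(degenerate & (beta[1] == 0), 0.0, t)
    if squeeze:
        return float(t[0]), float(p[0]), dof
    return t, p, dof
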