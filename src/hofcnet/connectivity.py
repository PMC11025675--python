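"""Low- and high-order functional connectivity matrices.

LOFC is the familiar region-pair Pearson correlation of ROI time series.
HOFC is a "correlation of correlations": each region's whole-brain
connectivity profile (its row of the Fisher-z LOFC matrix) is itself
correlated with every other region's profile, measuring topographical
similarity of connectivity rather than temporal synchronisation.  The
Fisher r-to-z transform is applied between the two rounds so the second
round of Pearson correlation operates on approximately normal quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

KINDS = ("LOFC", "zLOFC", "HOFC")


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region association matrix (diagonal stored 0)."""

    values: np.ndarray
    kind: str
    region_labels: list | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"values must be square, got shape {v.shape}")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("values must be symmetric to 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be stored as 0")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def lofc_matrix(series: np.ndarray, region_labels: list | None = None
                ) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of time-series columns."""
    sd = series.std(axis=0)
    scale = np.maximum(1.0, np.abs(series).max(axis=0))
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        names = ([region_labels[i] for i in dead] if region_labels
                 else dead.tolist())
        raise ValueError(f"zero-variance time series for region(s): {names}")
    r = np.corrcoef(series, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, "LOFC", region_labels)


def fisher_z(m: ConnectivityMatrix, clip: float = 0.999999) -> ConnectivityMatrix:
    """Elementwise Fisher r-to-z transform, z = arctanh(r)."""
    if m.kind != "LOFC":
        raise ValueError(f"fisher_z expects a LOFC matrix, got {m.kind}")
    r = m.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    n_clipped = int(np.sum(np.abs(r[off]) > clip))
    if n_clipped:
        logger.warning("clipped %d off-diagonal |r| values at %.6f before "
                       "arctanh", n_clipped, clip)
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, "zLOFC", m.region_labels)


def hofc_matrix(z: ConnectivityMatrix, exclude_pair: str = "both"
                ) -> ConnectivityMatrix:
    """Second-round Pearson correlation between connectivity profiles.

    Entry (i, j) correlates row i with row j of the z matrix.  With
    ``exclude_pair="both"`` (default) entries i and j are removed from both
    profiles, so the trivially-related self and cross entries cannot
    inflate the correlation; ``"none"`` keeps the full rows (the stored
    zero diagonals included).  A third variant that drops only each row's
    own diagonal entry would leave the two profiles indexed over different
    region sets, so it is not offered.
    """
    if z.kind != "zLOFC":
        raise ValueError(f"hofc_matrix expects a zLOFC matrix, got {z.kind}")
    if exclude_pair not in ("both", "none"):
        raise ValueError(f"exclude_pair must be 'both' or 'none', got {exclude_pair!r}")
    p = z.n_regions
    if p < 5:
        raise ValueError("HOFC needs at least 5 regions")
    zz = z.values

    if exclude_pair == "none":
        h = np.corrcoef(zz)
    else:
        # Closed-form pair exclusion.  With the diagonal stored as 0, the
        # cross-product over the reduced index set {k != i, j} equals the
        # full row inner product (the two excluded terms each contain a
        # diagonal factor), while row sums / sums of squares lose only z_ij.
        n = p - 2
        s = zz.sum(axis=1)
        q = (zz**2).sum(axis=1)
        cross = zz @ zz.T
        si = s[:, None] - zz          # sum of profile i excluding {i, j}
        sj = s[None, :] - zz
        qi = q[:, None] - zz**2
        qj = q[None, :] - zz**2
        num = n * cross - si * sj
        var_i = n * qi - si**2
        var_j = n * qj - sj**2
        denom = np.sqrt(np.maximum(var_i, 0.0) * np.maximum(var_j, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            h = num / denom
        degenerate = (denom <= 0) & ~np.eye(p, dtype=bool)
        if degenerate.any():
            logger.warning("%d HOFC entries had a constant profile after "
                           "exclusion; set to 0", int(degenerate.sum()))
            h[degenerate] = 0.0
    h = np.clip((h + h.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(h, 0.0)
    return ConnectivityMatrix(h, "HOFC", z.region_labels)


def connectivity_for_subject(series: np.ndarray, kinds=("LOFC", "HOFC"),
                             region_labels: list | None = None,
                             exclude_pair: str = "both") -> dict:
    """All requested connectivity kinds for one subject's time series."""
    lofc = lofc_matrix(series, region_labels)
    out = {}
    if "LOFC" in kinds:
        out["LOFC"] = lofc
    if "zLOFC" in kinds or "HOFC" in kinds:
        z = fisher_z(lofc)
        if "zLOFC" in kinds:
            out["zLOFC"] = z
        if "HOFC" in kinds:
            out["HOFC"] = hofc_matrix(z, exclude_pair)
    return out


def write_edge_matrix(m: np.ndarray, path) -> None:
    """Write a square matrix as whitespace-delimited text (.edge format)."""
    np.savetxt(path, m, fmt="%.10g", delimiter="\t")


def read_edge_matrix(path) -> np.ndarray:
    return np.loadtxt(path)
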