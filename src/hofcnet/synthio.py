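"""Synthetic two-group rs-fMRI cohorts and the on-disk cohort format.

The generator emulates a case/control hearing-loss study: per-subject ROI
time series over a 90-region parcellation grouped into five functional
modules (SMN, DMN, FPN, VN, SN), demographic covariates drawn from
group-specific distributions, and group differences planted as additive
shifts on named intra-/inter-module correlation blocks.  Everything that is
random flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODULE_NAMES = ("SMN", "DMN", "FPN", "VN", "SN")

#: Number of regions assigned to each module in the shipped default
#: partition.  The five-module grouping of the 90-region anatomical atlas
#: is a documented approximation (the exact region-to-module table is not
#: standardised); users replace it by passing their own ``partition``.
DEFAULT_MODULE_SIZES = {"SMN": 20, "DMN": 22, "FPN": 16, "VN": 14, "SN": 18}

GROUPS = ("patient", "control")


class CohortValidationError(ValueError):
    """A cohort table or time-series file violates the format contract."""


@dataclass(frozen=True)
class GroupProfile:
    """Mean/SD (or fraction) of each covariate for one group."""

    age: tuple[float, float]
    education: tuple[float, float]
    male_fraction: float
    pta_left: tuple[float, float] | None = None
    pta_right: tuple[float, float] | None = None


#: Covariate distributions of the emulated study population: presbycusis
#: patients (n=60) and age-matched normal-hearing controls (n=50).
DEFAULT_PROFILES = {
    "patient": GroupProfile(
        age=(62.75, 7.15),
        education=(10.93, 2.02),
        male_fraction=26 / 60,
        pta_left=(33.10, 4.40),
        pta_right=(33.34, 5.96),
    ),
    "control": GroupProfile(
        age=(61.08, 3.93),
        education=(10.78, 1.79),
        male_fraction=24 / 50,
        pta_left=(17.93, 5.84),
        pta_right=(17.40, 5.19),
    ),
}

#: Default planted group effects (module_a, module_b, delta, group).
#: Patients get stronger SMN-DMN and DMN-VN inter-module coupling and
#: weaker within-DMN coupling, giving the downstream modular / NBS stages a
#: known ground truth with the expected direction of effect.
DEFAULT_EFFECTS = (
    ("SMN", "DMN", 0.12, "patient"),
    ("DMN", "VN", 0.12, "patient"),
    ("DMN", "DMN", -0.12, "patient"),
)


@dataclass
class GeneratorConfig:
    """Full parameterisation of a synthetic cohort.

    ``effects`` entries are ``(module_a, module_b, delta, group)``: an
    additive shift on the correlation of every region pair in that block
    (within-module when ``module_a == module_b``) for the named group.
    """

    n_patient: int = 60
    n_control: int = 50
    n_regions: int = 90
    n_timepoints: int = 239  # 244 acquired volumes minus 5 dropped
    tr: float = 2.0
    r_within: float = 0.4
    r_between: float = 0.1
    effects: tuple = DEFAULT_EFFECTS
    ar_coef: float = 0.3
    seed: int = 0
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    module_sizes: dict = field(default_factory=lambda: dict(DEFAULT_MODULE_SIZES))
    confound_by_age: bool = False

    def __post_init__(self) -> None:
        if abs(self.r_within) >= 1 or abs(self.r_between) >= 1:
            raise ValueError("baseline correlations must lie in (-1, 1)")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if sum(self.module_sizes.values()) != self.n_regions:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes.values())}, "
                f"expected n_regions={self.n_regions}"
            )


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    gender: str
    education: float
    pta_left: float | None
    pta_right: float | None
    timeseries: np.ndarray  # T x P

    @property
    def pta_mean(self) -> float | None:
        if self.pta_left is None or self.pta_right is None:
            return None
        return (self.pta_left + self.pta_right) / 2.0


@dataclass
class CohortDataset:
    subjects: list
    region_labels: list
    partition: dict  # region label -> module name
    tr: float = 2.0

    def __post_init__(self) -> None:
        shapes = {s.timeseries.shape for s in self.subjects}
        if len(shapes) > 1:
            raise CohortValidationError(f"subjects disagree on (T, P): {sorted(shapes)}")
        missing = [r for r in self.region_labels if r not in self.partition]
        if missing:
            raise CohortValidationError(f"partition omits regions: {missing}")
        bad = sorted({m for m in self.partition.values()} - set(MODULE_NAMES))
        if bad:
            raise CohortValidationError(f"unknown module labels: {bad}")
        for g in GROUPS:
            if sum(s.group == g for s in self.subjects) < 2:
                raise CohortValidationError(f"group '{g}' has fewer than 2 subjects")

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].timeseries.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def groups(self) -> np.ndarray:
        """Boolean vector, True for patients, in subject order."""
        return np.array([s.group == "patient" for s in self.subjects])

    def covariates(self, names=("age", "gender", "education")) -> np.ndarray:
        """Numeric covariate matrix (gender coded M=1, F=0)."""
        cols = []
        for name in names:
            if name == "gender":
                cols.append([1.0 if s.gender == "M" else 0.0 for s in self.subjects])
            else:
                cols.append([float(getattr(s, name)) for s in self.subjects])
        return np.array(cols).T

    def timeseries_stack(self) -> np.ndarray:
        return np.stack([s.timeseries for s in self.subjects])


def default_partition(module_sizes: dict | None = None) -> tuple[list, dict]:
    """Region labels and the shipped region->module assignment."""
    sizes = dict(DEFAULT_MODULE_SIZES if module_sizes is None else module_sizes)
    labels, partition = [], {}
    idx = 0
    for module in MODULE_NAMES:
        for _ in range(sizes.get(module, 0)):
            idx += 1
            label = f"ROI{idx:03d}"
            labels.append(label)
            partition[label] = module
    return labels, partition


def _module_index_blocks(partition: dict, region_labels: list) -> dict:
    members = {m: [] for m in MODULE_NAMES}
    for i, r in enumerate(region_labels):
        members[partition[r]].append(i)
    return {m: np.array(v, dtype=int) for m, v in members.items() if v}


def nearest_positive_definite(matrix: np.ndarray, min_eig: float = 1e-6):
    """Clamp eigenvalues at ``min_eig`` and rescale to unit diagonal.

    Returns the repaired matrix and the max entrywise repair distance.
    """
    sym = (matrix + matrix.T) / 2.0
    repaired = sym
    for _ in range(100):
        vals, vecs = np.linalg.eigh(repaired)
        if vals.min() >= min_eig:
            break
        # rescaling to unit diagonal can nudge the spectrum back below the
        # floor, hence the (rapidly converging) clamp/rescale iteration
        repaired = (vecs * np.maximum(vals, min_eig)) @ vecs.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        np.fill_diagonal(repaired, 1.0)
    dist = float(np.max(np.abs(repaired - sym)))
    if dist > 0:
        logger.info("positive-definite repair applied (max entry change %.3g)",
                    dist)
    return repaired, dist


def build_group_covariance(config: GeneratorConfig, group: str,
                           effect_scale: float = 1.0) -> np.ndarray:
    """Target stationary correlation matrix for one group.

    Within-module pairs get ``r_within``, between-module pairs
    ``r_between``, plus the group's planted deltas (scaled by
    ``effect_scale``); the result is projected to the nearest
    positive-definite matrix with unit diagonal.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    labels, partition = default_partition(config.module_sizes)
    blocks = _module_index_blocks(partition, labels)
    p = config.n_regions
    target = np.full((p, p), config.r_between)
    for idx in blocks.values():
        target[np.ix_(idx, idx)] = config.r_within
    for mod_a, mod_b, delta, eff_group in config.effects:
        if eff_group != group:
            continue
        ia, ib = blocks[mod_a], blocks[mod_b]
        block = target[np.ix_(ia, ib)] + delta * effect_scale
        if np.any(np.abs(block) >= 1):
            raise ValueError(
                f"effect ({mod_a}, {mod_b}, {delta:+g}) pushes correlations "
                f"outside (-1, 1) in block {mod_a}-{mod_b}"
            )
        target[np.ix_(ia, ib)] = block
        if mod_a != mod_b:
            target[np.ix_(ib, ia)] = block.T
    np.fill_diagonal(target, 1.0)
    repaired, _ = nearest_positive_definite(target)
    return repaired


def sample_timeseries(cov: np.ndarray, n_timepoints: int, ar_coef: float,
                      seed) -> np.ndarray:
    """Stationary Gaussian AR(1) series with cross-sectional covariance ``cov``.

    The innovation covariance is scaled by ``1 - ar_coef**2`` so that the
    marginal covariance of every row equals ``cov`` exactly; the first row
    is drawn from the stationary distribution (no burn-in needed).
    """
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance is not positive definite; build it with "
            "build_group_covariance (which applies a PD repair)"
        ) from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = cov.shape[0]
    innov = rng.standard_normal((n_timepoints, p)) @ chol.T
    out = np.empty((n_timepoints, p))
    out[0] = innov[0]
    scale = np.sqrt(1.0 - ar_coef**2)
    for t in range(1, n_timepoints):
        out[t] = ar_coef * out[t - 1] + scale * innov[t]
    return out


def _sample_covariates(profile: GroupProfile, n: int, rng: np.random.Generator):
    age = rng.normal(*profile.age, size=n)
    edu = rng.normal(*profile.education, size=n)
    male = rng.random(n) < profile.male_fraction
    if profile.pta_left is not None:
        pta_l = rng.normal(*profile.pta_left, size=n)
        pta_r = rng.normal(*profile.pta_right, size=n)
    else:
        pta_l = pta_r = [None] * n
    return age, edu, male, pta_l, pta_r


def generate_cohort(config: GeneratorConfig | None = None) -> CohortDataset:
    """Draw a full synthetic cohort (both groups) under ``config.seed``."""
    config = config or GeneratorConfig()
    if config.n_patient < 2 or config.n_control < 2:
        raise ValueError("each group needs at least 2 subjects")
    if config.n_timepoints < 30:
        raise ValueError("n_timepoints must be >= 30 for correlation stability")
    rng = np.random.default_rng(config.seed)
    labels, partition = default_partition(config.module_sizes)

    subjects = []
    for group, n in (("patient", config.n_patient), ("control", config.n_control)):
        cov = build_group_covariance(config, group)
        age, edu, male, pta_l, pta_r = _sample_covariates(config.profiles[group], n, rng)
        for k in range(n):
            if config.confound_by_age:
                # connectivity effect mediated by age: per-subject target with
                # effect magnitude proportional to the subject's age z-score
                # relative to the pooled mean -> group difference disappears
                # once age is adjusted for.
                mu = np.mean([config.profiles[g].age[0] for g in GROUPS])
                sd = config.profiles[group].age[1]
                scale = (age[k] - mu) / sd if group == "patient" else 0.0
                cov_k = build_group_covariance(config, group, effect_scale=scale) \
                    if group == "patient" else cov
            else:
                cov_k = cov
            ts = sample_timeseries(cov_k, config.n_timepoints, config.ar_coef, rng)
            subjects.append(SubjectRecord(
                subject_id=f"{'pat' if group == 'patient' else 'ctl'}{k + 1:03d}",
                group=group,
                age=float(age[k]),
                gender="M" if male[k] else "F",
                education=float(edu[k]),
                pta_left=float(pta_l[k]) if pta_l[k] is not None else None,
                pta_right=float(pta_r[k]) if pta_r[k] is not None else None,
                timeseries=ts,
            ))
    return CohortDataset(subjects=subjects, region_labels=labels,
                         partition=partition, tr=config.tr)


# ---------------------------------------------------------------------------
# on-disk format: subjects.csv, partition.csv, ts/<subject_id>.csv

def write_cohort(dataset: CohortDataset, dir_path) -> None:
    from pathlib import Path

    root = Path(dir_path)
    (root / "ts").mkdir(parents=True, exist_ok=True)
    rows = []
    for order, s in enumerate(dataset.subjects):
        rows.append({
            "order": order, "subject_id": s.subject_id, "group": s.group,
            "age": s.age, "gender": s.gender, "education": s.education,
            "pta_left": s.pta_left, "pta_right": s.pta_right,
        })
        pd.DataFrame(s.timeseries, columns=dataset.region_labels).to_csv(
            root / "ts" / f"{s.subject_id}.csv", index=False)
    pd.DataFrame(rows).to_csv(root / "subjects.csv", index=False)
    pd.DataFrame({
        "region": dataset.region_labels,
        "module": [dataset.partition[r] for r in dataset.region_labels],
    }).to_csv(root / "partition.csv", index=False)
    with open(root / "tr.txt", "w") as fh:
        fh.write(repr(dataset.tr))


def read_cohort(dir_path) -> CohortDataset:
    from pathlib import Path

    root = Path(dir_path)
    part_df = pd.read_csv(root / "partition.csv")
    region_labels = part_df["region"].tolist()
    partition = dict(zip(part_df["region"], part_df["module"]))

    subj_df = pd.read_csv(root / "subjects.csv").sort_values("order")
    required = {"subject_id", "group", "age", "gender", "education"}
    missing_cols = required - set(subj_df.columns)
    if missing_cols:
        raise CohortValidationError(f"subjects.csv missing covariates: {sorted(missing_cols)}")

    tr_path = root / "tr.txt"
    tr = float(tr_path.read_text()) if tr_path.exists() else 2.0

    subjects = []
    p = len(region_labels)
    for _, row in subj_df.iterrows():
        ts = pd.read_csv(root / "ts" / f"{row.subject_id}.csv")
        if ts.shape[1] != p:
            unassigned = [c for c in ts.columns if c not in partition]
            if unassigned:
                raise CohortValidationError(
                    f"partition omits regions: {unassigned}")
            raise CohortValidationError(
                f"subject {row.subject_id}: time series has {ts.shape[1]} "
                f"columns, cohort has {p} regions")
        for name in ("age", "education"):
            if pd.isna(row[name]):
                raise CohortValidationError(
                    f"subject {row.subject_id}: missing covariate '{name}'")
        subjects.append(SubjectRecord(
            subject_id=str(row.subject_id), group=str(row.group),
            age=float(row.age), gender=str(row.gender),
            education=float(row.education),
            pta_left=None if pd.isna(row.get("pta_left")) else float(row.pta_left),
            pta_right=None if pd.isna(row.get("pta_right")) else float(row.pta_right),
            timeseries=ts.to_numpy(dtype=float),
        ))
    return CohortDataset(subjects=subjects, region_labels=region_labels,
                         partition=partition, tr=tr)
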