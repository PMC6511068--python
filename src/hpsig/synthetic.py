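"""Parametric Gaussian cohort simulator.

Real MCI/dementia cohorts with individual-level imaging features are
access-restricted, so every stage of the pipeline is exercised on synthetic
cohorts drawn from a parametric (Gaussian) bootstrap: the population is
stratified into 12 subgroups — 4 clinical labels (CN, sMCI, pMCI, AD), each
subdivided into 3 prognostic subclasses (negative, low confidence, high
confidence) — and, for each subgroup, participants are drawn from a
16-variable multivariate normal (age, sex, mean grey-matter volume, total
intracranial volume, 5 cognitive scores, 7 atrophy-subtype weights).  Draws
are clipped per variable to a realistic range and the sex variable is
binarized to the nearest of {0, 1} (exact ties to 1), in that order.

The module also plants recoverable structure for the other stages: voxel
maps built from subtype templates plus confound effects and noise, and
longitudinal ADAS13 trajectories with group-specific slopes.

The bundled default specification (:func:`default_cohort_spec`) is
hand-crafted to be plausible — group means follow published ADNI demographic
tables, with within-group severity shifts so that prognostic subclasses are
learnable — and is NOT the archived parameter set estimated on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DIAGNOSES, SUBCLASSES
from .subtyping import VoxelMapSet

VARIABLES = ["age", "sex", "mean_gmv", "tiv", "adas13", "mem", "exec",
             "bnt", "clock", "vbm_1", "vbm_2", "vbm_3", "vbm_4", "vbm_5",
             "vbm_6", "vbm_7"]
SEX_INDEX = VARIABLES.index("sex")


# ---------------------------------------------------------------------------
# specs

@dataclass
class SubgroupMoments:
    """Mean vector / covariance matrix / size of one (label x subclass) cell."""

    diagnosis: str
    subclass: str
    mean: np.ndarray                # (p,) native units
    cov: np.ndarray | None          # (p, p); None when size < 2 (flagged)
    size: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.shape != (len(self.mean), len(self.mean)):
                raise ValueError("covariance shape mismatch")
            if not np.allclose(self.cov, self.cov.T, atol=1e-8):
                raise ValueError("covariance must be symmetric")
        if self.size < 0:
            raise ValueError("size must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.diagnosis}/{self.subclass}"


@dataclass
class CohortSimSpec:
    """Everything needed to draw a synthetic cross-sectional cohort."""

    subgroups: list[SubgroupMoments]
    clip_min: np.ndarray            # (p,) native units
    clip_max: np.ndarray
    variables: list[str] = field(default_factory=lambda: list(VARIABLES))
    sex_index: int = SEX_INDEX

    def __post_init__(self):
        self.clip_min = np.asarray(self.clip_min, dtype=float)
        self.clip_max = np.asarray(self.clip_max, dtype=float)
        p = len(self.variables)
        if self.clip_min.shape != (p,) or self.clip_max.shape != (p,):
            raise ValueError("clipping bounds must match the variable count")
        if not (np.isfinite(self.clip_min).all() and np.isfinite(self.clip_max).all()):
            raise ValueError("clipping bounds must be finite")
        if (self.clip_min > self.clip_max).any():
            raise ValueError("clip_min must be <= clip_max")
        if not 0 <= self.sex_index < p:
            raise ValueError("sex_index out of range")

    @property
    def n_total(self) -> int:
        return sum(g.size for g in self.subgroups)

    # JSON round-trip so specs are shareable artifacts
    def to_json(self, path: str) -> None:
        payload = {
            "variables": self.variables,
            "sex_index": int(self.sex_index),
            "clip_min": self.clip_min.tolist(),
            "clip_max": self.clip_max.tolist(),
            "subgroups": [
                {"diagnosis": g.diagnosis, "subclass": g.subclass,
                 "size": int(g.size), "mean": g.mean.tolist(),
                 "cov": None if g.cov is None else g.cov.tolist()}
                for g in self.subgroups
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CohortSimSpec":
        with open(path) as fh:
            d = json.load(fh)
        groups = [SubgroupMoments(g["diagnosis"], g["subclass"],
                                  np.array(g["mean"]),
                                  None if g["cov"] is None else np.array(g["cov"]),
                                  g["size"])
                  for g in d["subgroups"]]
        return cls(groups, np.array(d["clip_min"]), np.array(d["clip_max"]),
                   variables=list(d["variables"]), sex_index=int(d["sex_index"]))


@dataclass
class MapSimSpec:
    """Planted-structure voxel-map generator parameters."""

    templates: np.ndarray           # (k, v) subtype template maps
    noise_sd: float = 0.1
    affinity_mean: float = 1.0
    affinity_sd: float = 0.0        # per-participant template scaling spread
    confound_effects: np.ndarray | None = None   # (n_confounds, v)

    def __post_init__(self):
        self.templates = np.asarray(self.templates, dtype=float)
        k, v = self.templates.shape
        if not (v >= k >= 1):
            raise ValueError("need v >= k >= 1")
        if self.noise_sd < 0 or self.affinity_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for i in range(k):
            for j in range(i + 1, k):
                if np.allclose(self.templates[i], self.templates[j]):
                    raise ValueError(f"templates {i} and {j} are identical")
        if self.confound_effects is not None:
            self.confound_effects = np.asarray(self.confound_effects, dtype=float)
            if self.confound_effects.shape[1] != v:
                raise ValueError("confound effect vectors must have v voxels")


@dataclass
class TrajectorySpec:
    """Longitudinal ADAS13 generator: per-risk-group baseline and slope.

    ``groups`` maps risk-group name -> (baseline ADAS13, slope in points per
    year).  Visits are months since baseline.  Each subject gets a random
    slope deviation (sd ``slope_sd``) and i.i.d. visit noise (``noise_sd``).
    """

    groups: dict[str, tuple[float, float]]
    visits_months: tuple[float, ...] = (0, 6, 12, 18, 24, 36)
    noise_sd: float = 1.5
    slope_sd: float = 0.5

    def __post_init__(self):
        v = np.asarray(self.visits_months, dtype=float)
        if len(v) and ((v < 0).any() or (np.diff(v) <= 0).any()):
            raise ValueError("visit months must be non-negative and strictly increasing")
        if self.noise_sd < 0 or self.slope_sd < 0:
            raise ValueError("standard deviations must be >= 0")


# ---------------------------------------------------------------------------
# default specification

# Diagnosis-level means (rows) for the 16 variables, loosely following
# published ADNI demographic tables (age, sex, ADAS13) with plausible values
# for the remaining measures.
_DIAG_MEANS = {
    #           age   sex  gmv    tiv   adas13  mem    exec   bnt   clock  vbm1..vbm7
    "CN":   [76.1, 0.52, 0.480, 1450,  9.5,  0.95,  0.70, 27.8, 4.7,
             -0.05, -0.04, 0.05, -0.05, 0.08, -0.10, 0.10],
    "sMCI": [72.5, 0.45, 0.465, 1460, 13.0,  0.35,  0.35, 25.9, 4.4,
             0.00, 0.00, 0.02, 0.00, 0.03, -0.02, 0.04],
    "pMCI": [73.7, 0.43, 0.450, 1455, 21.3, -0.25, -0.05, 24.2, 4.1,
             0.03, 0.03, -0.02, 0.04, -0.03, 0.07, -0.04],
    "AD":   [75.0, 0.49, 0.435, 1450, 30.0, -0.85, -0.55, 22.0, 3.6,
             0.06, 0.05, -0.05, 0.07, -0.08, 0.14, -0.09],
}

# Within-diagnosis severity shift separating prognostic subclasses: the
# high-confidence subclass sits further along the dementia-like direction.
_SEVERITY_DIR = np.array([0.5, 0.0, -0.010, 0.0, 3.5, -0.30, -0.22, -1.2, -0.25,
                          0.025, 0.020, -0.020, 0.025, -0.030, 0.050, -0.035])
_SUBCLASS_SHIFT = {"negative": -0.8, "low_confidence": 0.5, "high_confidence": 1.4}

_SDS = np.array([6.5, 0.5, 0.035, 140, 5.8, 0.55, 0.60, 3.5, 0.6,
                 0.12, 0.12, 0.12, 0.12, 0.12, 0.12, 0.12])

# Single-factor "disease severity" correlation structure, PSD by construction.
_LOADINGS = np.array([0.15, 0.0, -0.30, 0.0, 0.80, -0.75, -0.60, -0.50, -0.45,
                      0.30, 0.25, -0.20, 0.30, -0.25, 0.45, -0.40])

_SIZES = {
    "CN":   {"negative": 370, "low_confidence": 18, "high_confidence": 5},
    "sMCI": {"negative": 205, "low_confidence": 40, "high_confidence": 21},
    "pMCI": {"negative": 60, "low_confidence": 35, "high_confidence": 107},
    "AD":   {"negative": 15, "low_confidence": 35, "high_confidence": 204},
}

_CLIP_MIN = np.array([55, 0, 0.25, 1000, 0, -3, -3, 0, 0] + [-1.0] * 7)
_CLIP_MAX = np.array([95, 1, 0.65, 2100, 85, 3, 3, 30, 5] + [1.0] * 7)


def default_cohort_spec(scale: float = 1.0) -> CohortSimSpec:
    """Bundled plausible cohort specification (N = 1,115 at scale 1).

    ``scale`` shrinks every subgroup proportionally (minimum size 3) for
    fast smoke runs.  The spec is synthetic and hand-crafted; it is not an
    estimate from any real cohort.
    """
    R = np.outer(_LOADINGS, _LOADINGS)
    np.fill_diagonal(R, 1.0)
    groups = []
    for diag in DIAGNOSES:
        base = np.asarray(_DIAG_MEANS[diag], dtype=float)
        for sub in SUBCLASSES:
            mean = base + _SUBCLASS_SHIFT[sub] * _SEVERITY_DIR
            cov = R * np.outer(_SDS, _SDS)
            size = _SIZES[diag][sub]
            if scale != 1.0:
                size = max(3, int(round(size * scale)))
            groups.append(SubgroupMoments(diag, sub, mean, cov, size))
    return CohortSimSpec(groups, _CLIP_MIN.copy(), _CLIP_MAX.copy())


# ---------------------------------------------------------------------------
# operations

def fit_subgroup_moments(features: pd.DataFrame,
                         subclass_labels: pd.Series | np.ndarray | None = None,
                         variables: list[str] | None = None) -> list[SubgroupMoments]:
    """Empirical mean/covariance per (diagnosis x subclass) cell.

    Covariances use the unbiased n-1 divisor.  Cells with a single member
    are returned with ``cov=None`` (flagged: covariance undefined).  Any
    missing value among the modelled variables rejects the input.
    """
    variables = list(variables or VARIABLES)
    if subclass_labels is None:
        if "subclass" not in features.columns:
            raise ValueError("need a subclass column or explicit subclass labels")
        subclass_labels = features["subclass"]
    subclass_labels = np.asarray(subclass_labels)
    if len(subclass_labels) != len(features):
        raise ValueError("subclass labels not aligned with the feature table")
    if features["diagnosis"].isna().any() or pd.isna(subclass_labels).any():
        raise ValueError("every participant needs a clinical and a subclass label")
    X = features[variables]
    if X.isna().any().any():
        bad = [c for c in variables if X[c].isna().any()]
        raise ValueError(f"missing values among modelled variables: {bad}")
    out = []
    for diag in DIAGNOSES:
        for sub in SUBCLASSES:
            cell = X[(features["diagnosis"].to_numpy() == diag)
                     & (subclass_labels == sub)].to_numpy(float)
            if len(cell) == 0:
                continue
            mean = cell.mean(axis=0)
            cov = np.cov(cell, rowvar=False, ddof=1) if len(cell) >= 2 else None
            out.append(SubgroupMoments(diag, sub, mean, cov, len(cell)))
    return out


def _ensure_psd(cov: np.ndarray, label: str, repair: bool) -> np.ndarray:
    w, V = np.linalg.eigh(cov)
    if w.min() >= -1e-8 * max(1.0, w.max()):
        return cov
    if not repair:
        raise ValueError(f"covariance for subgroup {label} is not positive semidefinite "
                         f"(min eigenvalue {w.min():.3g}); pass repair=True to floor it")
    import warnings
    warnings.warn(f"flooring negative eigenvalues of subgroup {label} covariance at 0")
    return (V * np.maximum(w, 0.0)) @ V.T


def simulate_cohort(spec: CohortSimSpec, seed: int, repair: bool = False) -> pd.DataFrame:
    """Draw a cohort table from subgroup-conditional multivariate normals.

    For each subgroup, ``size`` vectors are drawn from N(mean, cov); every
    variable is then clipped to its bounds and the sex variable binarized to
    the nearest of {0, 1} (ties to 1).  The output carries the clinical
    label and the generating subclass as ground truth.  Identical
    spec + seed give bit-identical tables.
    """
    rng = np.random.default_rng(seed)
    rows, diags, subs = [], [], []
    for g in spec.subgroups:
        if g.size == 0:
            continue
        if g.cov is None:
            raise ValueError(f"subgroup {g.label} has no covariance (size < 2 at fit time)")
        cov = _ensure_psd(g.cov, g.label, repair)
        draws = rng.multivariate_normal(g.mean, cov, size=g.size,
                                        method="svd")
        rows.append(draws)
        diags += [g.diagnosis] * g.size
        subs += [g.subclass] * g.size
    X = np.vstack(rows) if rows else np.empty((0, len(spec.variables)))
    X = np.clip(X, spec.clip_min, spec.clip_max)
    # nearest of {0,1}; exact midpoint ties go to 1
    X[:, spec.sex_index] = (X[:, spec.sex_index] >= 0.5).astype(float)
    table = pd.DataFrame(X, columns=spec.variables)
    table.insert(0, "participant_id", [f"S{i:05d}" for i in range(len(table))])
    table.insert(1, "diagnosis", diags)
    table.insert(2, "subclass", subs)
    return table


def simulate_voxel_maps(spec: MapSimSpec, n_per_subtype: list[int] | np.ndarray,
                        seed: int, confounds: pd.DataFrame | None = None
                        ) -> tuple[VoxelMapSet, np.ndarray, np.ndarray]:
    """Voxel maps with planted subtype structure.

    Each participant assigned to subtype s gets
    ``affinity * template_s + confound_effects^T @ confound_values + noise``.
    Returns the map set, the ground-truth subtype labels (1..k) and the
    per-participant affinities, for recovery testing downstream.
    """
    n_per_subtype = np.asarray(n_per_subtype, dtype=int)
    k, v = spec.templates.shape
    if len(n_per_subtype) != k or (n_per_subtype < 1).any():
        raise ValueError("need a count >= 1 for each of the k subtypes")
    n = int(n_per_subtype.sum())
    if confounds is not None:
        if spec.confound_effects is None:
            raise ValueError("confound table given but spec has no confound effects")
        if len(confounds) != n:
            raise ValueError("confound table not row-aligned with output")
        C = confounds.to_numpy(float)
        if C.shape[1] != spec.confound_effects.shape[0]:
            raise ValueError("confound column count mismatch with effect vectors")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, k + 1), n_per_subtype)
    affinity = spec.affinity_mean + spec.affinity_sd * rng.standard_normal(n)
    values = affinity[:, None] * spec.templates[labels - 1]
    if confounds is not None:
        values = values + C @ spec.confound_effects
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.standard_normal((n, v))
    maps = VoxelMapSet(values, np.array([f"S{i:05d}" for i in range(n)]))
    return maps, labels, affinity


def simulate_trajectories(spec: TrajectorySpec,
                          group_assignment: pd.Series,
                          seed: int) -> pd.DataFrame:
    """Long-format ADAS13 visit table.

    ``group_assignment`` maps participant id -> risk group.  For subject i
    in group g:  ADAS13(t) = baseline_g + (slope_g + b_i) * t/12 + noise,
    with b_i ~ N(0, slope_sd^2) shared across that subject's visits.
    """
    unknown = set(group_assignment) - set(spec.groups)
    if unknown:
        raise ValueError(f"unknown risk group(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    t = np.asarray(spec.visits_months, dtype=float)
    recs = []
    for pid, grp in group_assignment.items():
        baseline, slope = spec.groups[grp]
        b = spec.slope_sd * rng.standard_normal()
        noise = spec.noise_sd * rng.standard_normal(len(t))
        scores = baseline + (slope + b) * t / 12.0 + noise
        for month, score in zip(t, scores):
            recs.append((pid, grp, month, score))
    return pd.DataFrame(recs, columns=["participant_id", "group", "visit_month", "adas13"])


def naive_group_slopes(visits: pd.DataFrame) -> pd.Series:
    """Per-group mean of per-subject OLS slopes (points per year).

    Generator-validation helper only; real longitudinal inference belongs in
    a dedicated mixed-model package.
    """
    def subject_slope(df):
        t = df["visit_month"].to_numpy(float) / 12.0
        y = df["adas13"].to_numpy(float)
        if len(t) < 2:
            return np.nan
        return np.polyfit(t, y, 1)[0]

    slopes = visits.groupby(["group", "participant_id"]).apply(
        subject_slope, include_groups=False)
    return slopes.groupby(level="group").mean()
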