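"""Grey-matter atrophy subtyping.

Individual modulated grey-matter maps (one value per voxel per participant,
produced upstream by a VBM pipeline) are residualized against nuisance
covariates (age, sex, mean grey-matter volume, total intracranial volume),
compared pairwise with a spatial Pearson correlation, and clustered with
Ward's hierarchical method.  Each subtype is the average residual map of one
cluster, and any participant — training or held-out — receives a vector of
*subtype weights*: spatial correlations between their residual map and each
subtype average.  Weights are continuous affinity measures and serve as
modelling features downstream.

Held-out participants are residualized with the coefficients estimated on
the training sample (stored in the model), never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

CONFOUND_COLUMNS = ["age", "sex", "mean_gmv", "tiv"]


@dataclass
class VoxelMapSet:
    """n participants x v voxels of modulated grey-matter values.

    ``mask`` is a boolean array over a named 3-D grid (optional; when absent
    the maps are treated as an abstract flat matrix).  ``affine`` and
    ``shape`` carry spatial metadata for NIfTI round-trips.
    """

    values: np.ndarray                      # (n, v)
    ids: np.ndarray                         # (n,)
    mask: np.ndarray | None = None          # (v,) bool or flat index
    shape: tuple | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (participants x voxels) matrix")
        n, v = self.values.shape
        if n < 1 or v < 2:
            raise ValueError("need at least 1 participant and 2 voxels")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in voxel maps")
        if len(self.ids) != n:
            raise ValueError("ids not aligned with rows")
        if len(np.unique(self.ids)) != n:
            raise ValueError("participant ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]


@dataclass
class SubtypeModel:
    """Fitted subtyping stage: confound fit, cluster labels, subtype maps."""

    k: int
    coef: np.ndarray                # (confounds+1, v) OLS coefficients, row 0 = intercept
    subtype_maps: np.ndarray        # (k, v) mean residual map per cluster
    similarity: np.ndarray          # (n, n) training similarity
    labels: np.ndarray              # (n,) in 1..k, renumbered by descending size
    mask: np.ndarray | None = None
    train_ids: np.ndarray | None = None


def _design_matrix(confounds: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in CONFOUND_COLUMNS if c in confounds.columns]
    if not cols:
        raise ValueError(f"confound table must contain some of {CONFOUND_COLUMNS}")
    if confounds[cols].isna().any().any():
        raise ValueError("missing values in confound table")
    X = np.column_stack([np.ones(len(confounds))] + [confounds[c].to_numpy(float) for c in cols])
    names = ["intercept"] + cols
    # full column rank required; name the offending columns otherwise
    if np.linalg.matrix_rank(X) < X.shape[1]:
        r = np.linalg.matrix_rank(X)
        raise ValueError(
            f"confound design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"check for collinear columns among {names}"
        )
    return X, names


def regress_confounds(maps: VoxelMapSet, confounds: pd.DataFrame
                      ) -> tuple[VoxelMapSet, np.ndarray]:
    """Voxel-wise OLS removal of nuisance covariates.

    Fits, at every voxel independently, grey-matter value ~ intercept + age +
    sex + mean GMV + TIV, and returns the residual maps together with the
    coefficient matrix (rows: intercept then confounds; columns: voxels) for
    residualizing new participants later.
    """
    if len(confounds) != maps.n:
        raise ValueError("confound table not row-aligned with maps")
    X, _ = _design_matrix(confounds)
    coef, *_ = np.linalg.lstsq(X, maps.values, rcond=None)
    residuals = maps.values - X @ coef
    res = VoxelMapSet(residuals, maps.ids, mask=maps.mask,
                      shape=maps.shape, affine=maps.affine)
    return res, coef


def apply_confound_model(maps: VoxelMapSet, confounds: pd.DataFrame,
                         coef: np.ndarray) -> VoxelMapSet:
    """Residualize maps with stored (training-sample) coefficients."""
    if len(confounds) != maps.n:
        raise ValueError("confound table not row-aligned with maps")
    X, _ = _design_matrix(confounds)
    if X.shape[1] != coef.shape[0]:
        raise ValueError("confound model dimension mismatch")
    return VoxelMapSet(maps.values - X @ coef, maps.ids, mask=maps.mask,
                       shape=maps.shape, affine=maps.affine)


def _rowwise_standardize(values: np.ndarray, who: np.ndarray) -> np.ndarray:
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    zero = norms == 0
    if zero.any():
        raise ValueError(
            f"zero-variance map(s) for participant(s) {list(np.asarray(who)[zero][:5])}"
        )
    return centred / norms[:, None]


def similarity_matrix(residuals: VoxelMapSet) -> np.ndarray:
    """Spatial Pearson correlation between all pairs of individual maps."""
    Z = _rowwise_standardize(residuals.values, residuals.ids)
    S = Z @ Z.T
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def cluster_participants(similarity: np.ndarray, k: int) -> np.ndarray:
    """Ward clustering of the similarity structure, cut at exactly k clusters.

    Ward linkage needs dissimilarities; the correlation matrix is converted
    elementwise as d = 1 - r (the common convention for correlation
    matrices).  Labels are integers 1..k renumbered by descending cluster
    size, ties broken by the lowest member index, so the labelling is
    reproducible.
    """
    n = similarity.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    D = 1.0 - similarity
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    raw = cut_tree(Z, n_clusters=k).ravel()
    return _renumber_by_size(raw)


def _renumber_by_size(raw: np.ndarray) -> np.ndarray:
    uniq = np.unique(raw)
    order = sorted(uniq, key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


def compute_subtype_maps(residuals: VoxelMapSet, labels: np.ndarray) -> np.ndarray:
    """Subtype c = average residual map over cluster c; (k, v) matrix."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != residuals.n:
        raise ValueError("labels not aligned with maps")
    k = labels.max()
    expected = set(range(1, k + 1))
    present = set(np.unique(labels))
    if present != expected:
        raise ValueError(f"labels must cover 1..{k} with no empty cluster; got {sorted(present)}")
    return np.vstack([residuals.values[labels == c].mean(axis=0) for c in range(1, k + 1)])


def compute_weights(model: SubtypeModel, maps: VoxelMapSet,
                    confounds: pd.DataFrame) -> pd.DataFrame:
    """Subtype weights: spatial correlation of each residual map with each subtype.

    New maps are residualized with the model's stored confound coefficients
    (not refit), then Pearson-correlated against every subtype average map.
    Returns a DataFrame indexed by participant id with columns vbm_1..vbm_k;
    every entry lies in [-1, 1].
    """
    if model.mask is not None and maps.mask is not None:
        if maps.mask.shape != model.mask.shape or not np.array_equal(maps.mask, model.mask):
            raise ValueError("voxel mask mismatch between model and maps")
    if maps.v != model.subtype_maps.shape[1]:
        raise ValueError("voxel dimension mismatch between model and maps")
    residuals = apply_confound_model(maps, confounds, model.coef)
    Zr = _rowwise_standardize(residuals.values, residuals.ids)
    Zs = _rowwise_standardize(model.subtype_maps, np.arange(1, model.k + 1))
    W = np.clip(Zr @ Zs.T, -1.0, 1.0)
    cols = [f"vbm_{i}" for i in range(1, model.k + 1)]
    return pd.DataFrame(W, index=pd.Index(maps.ids, name="participant_id"), columns=cols)


def fit_subtypes(maps: VoxelMapSet, confounds: pd.DataFrame, k: int = 7) -> SubtypeModel:
    """Full subtyping fit: confound regression, similarity, Ward cut, averages."""
    residuals, coef = regress_confounds(maps, confounds)
    S = similarity_matrix(residuals)
    labels = cluster_participants(S, k)
    subtype_maps = compute_subtype_maps(residuals, labels)
    return SubtypeModel(k=k, coef=coef, subtype_maps=subtype_maps, similarity=S,
                        labels=labels, mask=maps.mask, train_ids=maps.ids.copy())


def save_maps_nifti(maps: VoxelMapSet, path: str) -> None:
    """Write a map set as a 4-D NIfTI volume (requires spatial metadata)."""
    import nibabel as nib

    if maps.shape is None or maps.mask is None:
        raise ValueError("spatial metadata (shape, mask) required for NIfTI export")
    affine = maps.affine if maps.affine is not None else np.eye(4)
    vol = np.zeros((*maps.shape, maps.n))
    flat = vol.reshape(-1, maps.n)
    flat[np.flatnonzero(maps.mask.ravel())] = maps.values.T
    nib.save(nib.Nifti1Image(vol, affine), path)


def load_maps_nifti(path: str, mask_path: str, ids=None) -> VoxelMapSet:
    """Read a 4-D NIfTI volume plus binary mask into a VoxelMapSet."""
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(nib.load(mask_path).dataobj) > 0
    values = data.reshape(-1, data.shape[-1])[mask.ravel()].T
    if ids is None:
        ids = np.arange(values.shape[0])
    return VoxelMapSet(values, np.asarray(ids), mask=mask,
                       shape=data.shape[:-1], affine=img.affine)
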