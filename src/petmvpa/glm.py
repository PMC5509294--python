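"""Stage 1: voxel-wise ANCOVA t-map and cluster-extent mask.

A mass-univariate linear model is fitted independently at every in-mask
voxel: intensity ~ group + centered age + intercept.  The one-sided
t-contrast healthy-minus-disease picks out hypometabolism (disease group
lower), mirroring the convention that only decreased uptake enters the
discriminative mask.  Voxels passing a strict p < p_voxel threshold are
grouped into connected components (18-connectivity by default: faces and
edges, not corners) and only components with at least k_min voxels are
retained, yielding the binary mask and a per-cluster report (size, peak
t, peak mm coordinate) sorted by descending cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .cohort import Cohort
from .grid import GridSpec

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

# p clipped away from {0, 1} before the normal-quantile transform so z stays finite
_P_EPS = 1e-300


@dataclass
class DesignMatrix:
    """Per-subject design: group indicator, centered age, intercept.

    ``contrast`` selects healthy-minus-disease on the group column and
    puts zero weight on nuisance columns, so positive t means lower
    uptake in the disease group.
    """

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    @property
    def df(self) -> int:
        return self.n - self.rank


@dataclass
class StatMap:
    """Per-voxel t, one-sided p and equivalent normal quantile z.

    Values outside the analysis mask are t=0, p=1 by convention.
    """

    t: np.ndarray
    df: int
    p: np.ndarray
    z: np.ndarray
    grid: GridSpec


@dataclass
class ClusterMask:
    """Binary discriminative mask with labeled clusters and a report.

    ``labels`` assigns 1..n_clusters (0 = background) in descending
    cluster-size order; ``report`` has one row per retained cluster with
    columns cluster_id, K, peak_x_mm, peak_y_mm, peak_z_mm, peak_t,
    p_peak, sorted by descending K.
    """

    mask: np.ndarray
    labels: np.ndarray
    report: pd.DataFrame
    grid: GridSpec

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def write_report(self, path) -> None:
        self.report.to_csv(path, sep="\t", index=False)


def build_design(cohort: Cohort, covariates: tuple[str, ...] = ("age",)) -> DesignMatrix:
    """Design with healthy-group indicator, centered age, intercept.

    A constant age column (zero variance after centering) would make the
    design rank-deficient; it is dropped with a warning.  A single-group
    cohort is an error.
    """
    labels = cohort.labels
    if len(set(labels.tolist())) < 2:
        raise ValueError("cohort must contain both groups to fit a group contrast")
    healthy = (labels == -1).astype(float)
    cols = [healthy]
    names = ["group_healthy"]
    if "age" in covariates:
        age_c = cohort.ages - cohort.ages.mean()
        if np.allclose(age_c, 0.0):
            warnings.warn(
                "age is constant across the cohort; dropping the age column "
                "to keep the design full rank",
                stacklevel=2,
            )
        else:
            cols.append(age_c)
            names.append("age_centered")
    cols.append(np.ones(len(cohort)))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0  # healthy minus disease
    return DesignMatrix(X=X, columns=names, contrast=contrast)


def fit_voxelwise_glm(
    cohort: Cohort,
    design: DesignMatrix,
    analysis_mask: np.ndarray | None = None,
) -> StatMap:
    """Independent OLS at every voxel; t = c'b / sqrt(s2 c'(X'X)^-1 c).

    One-sided p = P(T_df > t) for the healthy-greater-than-disease
    direction, z = the standard-normal quantile at 1-p.  Zero-variance
    voxels (e.g. all-zero background) get t=0, p=1.
    """
    if analysis_mask is None:
        analysis_mask = cohort.brain_mask
    X = design.X
    c = design.contrast
    df = design.df
    if df < 1:
        raise ValueError(f"residual degrees of freedom must be >= 1, got {df}")

    flat_idx = np.flatnonzero(analysis_mask.ravel())
    Y = cohort.data_matrix()[:, flat_idx]

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    var_c = float(c @ XtX_inv @ c)
    cb = c @ beta

    denom = np.sqrt(np.maximum(sigma2 * var_c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, cb / np.where(denom > 0, denom, 1.0), 0.0)
    degenerate = denom == 0

    p = stats.t.sf(t, df)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    z = stats.norm.isf(np.clip(p, _P_EPS, 1.0 - 1e-16))

    shape = cohort.grid.shape
    t_vol = np.zeros(shape)
    p_vol = np.ones(shape)
    z_vol = np.full(shape, stats.norm.isf(1.0 - 1e-16))
    t_vol.ravel()[flat_idx] = t
    p_vol.ravel()[flat_idx] = p
    z_vol.ravel()[flat_idx] = z
    return StatMap(t=t_vol, df=df, p=p_vol, z=z_vol, grid=cohort.grid)


def threshold_voxels(statmap: StatMap, p_voxel: float = 0.005) -> np.ndarray:
    """Binary volume of voxels with p strictly below the threshold."""
    return statmap.p < p_voxel


def label_clusters(binary: np.ndarray, connectivity: int = 18) -> np.ndarray:
    """Connected components of a binary volume, labels 1..n.

    Labels are assigned in raster-scan order of each component's first
    voxel, so the output is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    labeled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n == 0:
        return labeled
    flat = labeled.ravel()
    nz = np.flatnonzero(flat)
    order_labels, first_idx = np.unique(flat[nz], return_index=True)
    remap = np.zeros(n + 1, dtype=labeled.dtype)
    remap[order_labels[np.argsort(first_idx)]] = np.arange(1, n + 1)
    return remap[labeled]


def apply_extent_threshold(
    labeled: np.ndarray,
    statmap: StatMap,
    k_min: int = 200,
) -> ClusterMask:
    """Keep clusters with at least k_min voxels (inclusive bound).

    The retained clusters are relabeled 1..m in descending-size order
    (ties broken by raster position of the first voxel) and summarized
    one row each: voxel count K, peak t, the peak's mm coordinate, and
    the peak's one-sided p.  An empty surviving mask is valid but warned
    about — the decoder refuses it downstream.
    """
    grid = statmap.grid
    n = int(labeled.max())
    sizes = np.bincount(labeled.ravel(), minlength=n + 1)
    keep = [lab for lab in range(1, n + 1) if sizes[lab] >= k_min]
    keep.sort(key=lambda lab: -sizes[lab])

    out_labels = np.zeros_like(labeled)
    rows = []
    for new_id, lab in enumerate(keep, start=1):
        comp = labeled == lab
        out_labels[comp] = new_id
        t_in = np.where(comp, statmap.t, -np.inf)
        peak_flat = int(np.argmax(t_in))
        pk = np.unravel_index(peak_flat, labeled.shape)
        peak_mm = grid.voxel_to_mm(np.array(pk))
        rows.append(
            {
                "cluster_id": new_id,
                "K": int(sizes[lab]),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_t": float(statmap.t[pk]),
                "p_peak": float(statmap.p[pk]),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["cluster_id", "K", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                 "peak_t", "p_peak"],
    )
    mask = out_labels > 0
    if not mask.any():
        warnings.warn(
            f"no cluster survived the extent threshold k_min={k_min}; "
            "the discriminative mask is empty",
            stacklevel=2,
        )
    return ClusterMask(mask=mask, labels=out_labels, report=report, grid=grid)


def build_mask(
    cohort: Cohort,
    p_voxel: float = 0.005,
    k_min: int = 200,
    connectivity: int = 18,
) -> tuple[ClusterMask, StatMap]:
    """Full stage 1 on a preprocessed cohort: design, t-map, thresholds."""
    design = build_design(cohort)
    statmap = fit_voxelwise_glm(cohort, design)
    binary = threshold_voxels(statmap, p_voxel) & cohort.brain_mask
    labeled = label_clusters(binary, connectivity)
    cluster_mask = apply_extent_threshold(labeled, statmap, k_min)
    return cluster_mask, statmap
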