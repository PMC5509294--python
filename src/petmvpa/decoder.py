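"""Stage 2: linear maximum-margin decoding on masked voxel intensities.

Subjects become rows of a feature matrix whose columns are the mask's
voxels in fixed raster order; a soft-margin linear SVM (hinge loss, L2
penalty, C = 1 by default) is fitted on the training cohort with disease
coded +1 so a positive decision score means "classified as disease".
Features are the globally normalized intensities as-is — no per-feature
standardization — so the learned weights relate directly to raw
intensity, and the weight vector can be scattered back into the volume
as an interpretable weight map.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .cohort import Cohort
from .glm import ClusterMask, StatMap
from .grid import GridSpec


def mask_checksum(mask: np.ndarray) -> str:
    """SHA-256 of the mask's shape and voxel content; ties a model to its mask."""
    h = hashlib.sha256()
    h.update(np.asarray(mask.shape, dtype=np.int64).tobytes())
    h.update(np.packbits(mask.astype(bool).ravel()).tobytes())
    return h.hexdigest()


@dataclass
class FeatureMatrix:
    """Subjects x masked-voxels intensity matrix with labels.

    ``voxel_index`` maps each column to its flat raster index on the
    grid; labels are +1 disease / -1 healthy.
    """

    X: np.ndarray
    labels: np.ndarray
    voxel_index: np.ndarray
    subject_ids: list[str]
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.voxel_index.size or self.X.shape[1] == 0:
            raise ValueError("feature columns must match a nonempty voxel index")
        if not set(np.unique(self.labels).tolist()) <= {-1, 1}:
            raise ValueError("labels must be coded +1 (disease) / -1 (healthy)")


@dataclass
class DecoderModel:
    """Linear decoder: per-masked-voxel weights w, intercept b.

    Decision score for a subject with masked intensities x is
    s = w.x + b; s > 0 (and the s = 0 tie, by logged convention)
    classifies as disease.
    """

    w: np.ndarray
    b: float
    C: float
    voxel_index: np.ndarray
    grid: GridSpec
    mask_sha256: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if self.w.size != self.voxel_index.size:
            raise ValueError("one weight per masked voxel required")

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.w, dtype=np.float64).tobytes())
        h.update(np.float64(self.b).tobytes())
        return h.hexdigest()

    def to_json(self, path) -> None:
        payload = {
            "w": np.asarray(self.w, dtype=float).tolist(),
            "b": float(self.b),
            "C": float(self.C),
            "voxel_index": np.asarray(self.voxel_index, dtype=int).tolist(),
            "grid": {
                "shape": list(self.grid.shape),
                "voxel_size_mm": self.grid.voxel_size_mm,
                "origin_mm": list(self.grid.origin_mm),
            },
            "mask_sha256": self.mask_sha256,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DecoderModel":
        with open(path) as fh:
            d = json.load(fh)
        grid = GridSpec(tuple(d["grid"]["shape"]), d["grid"]["voxel_size_mm"],
                        tuple(d["grid"]["origin_mm"]))
        return cls(w=np.asarray(d["w"], dtype=float), b=float(d["b"]),
                   C=float(d["C"]), voxel_index=np.asarray(d["voxel_index"], dtype=int),
                   grid=grid, mask_sha256=d.get("mask_sha256", ""))


@dataclass
class ScoreSet:
    """Per-subject decision scores with predicted and true labels."""

    subject_ids: list[str]
    scores: np.ndarray
    predicted: np.ndarray  # +1 disease / -1 healthy
    true: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "score": self.scores,
                "predicted": np.where(self.predicted > 0, "disease", "healthy"),
                "true": np.where(self.true > 0, "disease", "healthy"),
            }
        )

    def group_summary(self) -> pd.DataFrame:
        """Score distribution per true group — the boxplot view."""
        df = pd.DataFrame({"score": self.scores,
                           "group": np.where(self.true > 0, "disease", "healthy")})
        return df.groupby("group")["score"].describe()


def extract_features(cohort: Cohort, mask: ClusterMask | np.ndarray) -> FeatureMatrix:
    """Masked voxel intensities per subject, columns in raster order.

    Values are the preprocessed intensities as-is (no standardization).
    An empty mask or a grid mismatch is an error.
    """
    mask_arr = mask.mask if isinstance(mask, ClusterMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != tuple(cohort.grid.shape):
        raise ValueError(
            f"mask shape {mask_arr.shape} does not match cohort grid {cohort.grid.shape}"
        )
    voxel_index = np.flatnonzero(mask_arr.ravel())
    if voxel_index.size == 0:
        raise ValueError("discriminative mask is empty; cannot extract features")
    X = cohort.data_matrix()[:, voxel_index]
    return FeatureMatrix(X=X, labels=cohort.labels, voxel_index=voxel_index,
                         subject_ids=cohort.ids, grid=cohort.grid)


def train_linear_svm(features: FeatureMatrix, C: float = 1.0,
                     tol: float = 1e-6) -> DecoderModel:
    """Soft-margin linear SVM: minimize 0.5||w||^2 + C sum hinge.

    The convex dual is solved deterministically to ``tol``; the returned
    weights are oriented so that a positive score predicts disease.
    """
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    labs = np.unique(features.labels)
    if labs.size < 2:
        raise ValueError("training features must contain both classes")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(features.X, features.labels)
    # classes_ is sorted [-1, +1], so decision_function > 0 already means disease
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])
    return DecoderModel(w=w, b=b, C=C, voxel_index=features.voxel_index,
                        grid=features.grid)


def decision_scores(model: DecoderModel, features: FeatureMatrix) -> ScoreSet:
    """Dot-product decision values s = w.x + b per subject.

    s >= 0 predicts disease (the s = 0 tie resolves to disease)."""
    if features.X.shape[1] != model.w.size or not np.array_equal(
        features.voxel_index, model.voxel_index
    ):
        raise ValueError("feature columns do not match the model's voxel index")
    s = features.X @ model.w + model.b
    predicted = np.where(s >= 0, 1, -1)
    return ScoreSet(subject_ids=features.subject_ids, scores=s,
                    predicted=predicted, true=features.labels.copy())


def weight_map(model: DecoderModel, mask: ClusterMask | np.ndarray,
               grid: GridSpec) -> np.ndarray:
    """Scatter the weight vector back into the volume; 0 outside the mask."""
    mask_arr = mask.mask if isinstance(mask, ClusterMask) else np.asarray(mask, dtype=bool)
    vol = np.zeros(grid.shape)
    vol.ravel()[model.voxel_index] = model.w
    if not np.array_equal(np.flatnonzero(mask_arr.ravel()), model.voxel_index):
        raise ValueError("mask does not match the model's voxel index")
    return vol


def weight_vs_stat(model: DecoderModel, statmap: StatMap,
                   mask: ClusterMask | np.ndarray) -> tuple[pd.DataFrame, float | None]:
    """Pair each masked voxel's z with its decoder weight.

    Returns the per-voxel table and the Spearman rank correlation
    between z and w (None when z is constant, where the correlation is
    undefined).  On hypometabolic signal the correlation is negative:
    the stronger the univariate evidence for reduced uptake, the more
    negative the weight.
    """
    mask_arr = mask.mask if isinstance(mask, ClusterMask) else np.asarray(mask, dtype=bool)
    voxel_index = np.flatnonzero(mask_arr.ravel())
    if not np.array_equal(voxel_index, model.voxel_index):
        raise ValueError("mask does not match the model's voxel index")
    z = statmap.z.ravel()[voxel_index]
    table = pd.DataFrame({"voxel_index": voxel_index, "z": z, "w": model.w})
    if np.allclose(z, z[0]):
        return table, None
    rho = float(stats.spearmanr(z, model.w).statistic)
    return table, rho
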