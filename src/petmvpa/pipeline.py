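"""End-to-end orchestration: simulate -> preprocess -> mask -> train -> score -> evaluate.

The pipeline mirrors a two-branch design: the training branch builds the
discriminative mask and the decoder from training subjects only; the
testing branch applies the frozen mask and model to held-out subjects
and reports the confusion matrix, the five diagnostic metrics, and the
Mann-Whitney comparison of decision scores.  Strict train/test
separation is the central validity property and is enforced by disjoint
subject ids plus an explicit check before scoring.

All randomness flows from the single config seed through named
substreams (training cohort, testing cohort), so a config fully
determines every artifact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, ClusterSpec, CohortSpec, generate_cohort
from .decoder import (
    DecoderModel,
    ScoreSet,
    decision_scores,
    extract_features,
    mask_checksum,
    train_linear_svm,
    weight_map,
)
from .evaluate import ConfusionMatrix, Metrics, confusion, metrics, score_separation
from .glm import ClusterMask, StatMap, build_mask
from .grid import GridSpec, save_volume
from .preprocess import NormalizationParams, SmoothingParams, preprocess_cohort

#: Desk-scale default lattice (2 mm voxels), centred on the origin.
DEFAULT_SHAPE = (48, 56, 48)


def default_grid(shape: tuple[int, int, int] = DEFAULT_SHAPE,
                 voxel_size_mm: float = 2.0) -> GridSpec:
    """Grid centred on (0,0,0) mm, the template-space convention."""
    origin = tuple(-(s - 1) * voxel_size_mm / 2.0 for s in shape)
    return GridSpec(shape=shape, voxel_size_mm=voxel_size_mm, origin_mm=origin)


def default_clusters(effect_fraction: float = 0.3) -> tuple[ClusterSpec, ...]:
    """Three spheres inside the phantom brain, loosely emulating a
    multi-focal hypometabolic pattern (posterior, temporal, frontal)."""
    return (
        ClusterSpec(center_mm=(-20.0, -30.0, -10.0), radius_mm=12.0,
                    effect_fraction=effect_fraction),
        ClusterSpec(center_mm=(24.0, 20.0, 8.0), radius_mm=10.0,
                    effect_fraction=effect_fraction),
        ClusterSpec(center_mm=(0.0, 30.0, -16.0), radius_mm=8.0,
                    effect_fraction=effect_fraction),
    )


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; the seed pins all randomness."""

    train_spec: CohortSpec
    test_spec: CohortSpec
    grid: GridSpec = field(default_factory=default_grid)
    baseline: float = 100.0
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    p_voxel: float = 0.005
    k_min: int = 200
    connectivity: int = 18
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_voxel < 1):
            raise ValueError("p_voxel must be in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")

    def resolved_specs(self) -> tuple[CohortSpec, CohortSpec]:
        """Cohort specs with seeds derived from the config seed when unset."""
        root = np.random.SeedSequence(self.seed)
        tr_seed, te_seed = (
            int(child.generate_state(1)[0] % (2**31)) for child in root.spawn(2)
        )
        tr = self.train_spec if self.train_spec.seed is not None else replace(
            self.train_spec, seed=tr_seed)
        te = self.test_spec if self.test_spec.seed is not None else replace(
            self.test_spec, seed=te_seed)
        return tr, te

    def echo(self) -> dict:
        tr, te = self.resolved_specs()
        return {
            "grid": {"shape": list(self.grid.shape),
                     "voxel_size_mm": self.grid.voxel_size_mm,
                     "origin_mm": list(self.grid.origin_mm)},
            "baseline": self.baseline,
            "fwhm_mm": self.smoothing.fwhm_mm,
            "target_mean": self.normalization.target_mean,
            "p_voxel": self.p_voxel,
            "k_min": self.k_min,
            "connectivity": self.connectivity,
            "C": self.C,
            "seed": self.seed,
            "train": {"n_disease": tr.n_disease, "n_healthy": tr.n_healthy,
                      "seed": tr.seed},
            "test": {"n_disease": te.n_disease, "n_healthy": te.n_healthy,
                     "seed": te.seed},
        }


@dataclass
class TrainingArtifacts:
    mask: ClusterMask
    statmap: StatMap
    model: DecoderModel
    train_ids: list[str]
    train_scores: ScoreSet
    log: list[str]


@dataclass
class RunReport:
    """Everything the testing branch reports, recomputable from intermediates."""

    config: dict
    version: str
    cluster_report: pd.DataFrame
    model_checksum: str
    cm: ConfusionMatrix
    metrics: Metrics
    scores: pd.DataFrame
    mann_whitney: dict
    log: list[str]

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "cluster_report": self.cluster_report.to_dict(orient="records"),
            "model_checksum": self.model_checksum,
            "counts": {"TP": self.cm.TP, "FN": self.cm.FN,
                       "FP": self.cm.FP, "TN": self.cm.TN},
            "metrics": self.metrics.as_dict(),
            "metrics_percent": self.metrics.as_percent(decimals=1),
            "mann_whitney": self.mann_whitney,
            "scores": self.scores.to_dict(orient="records"),
            "log": self.log,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=float)


def run_training(config: RunConfig,
                 train_cohort: Cohort | None = None) -> TrainingArtifacts:
    """Training branch: build mask and decoder from training subjects only."""
    log: list[str] = []
    tr_spec, _ = config.resolved_specs()
    if train_cohort is None:
        train_cohort, _ = generate_cohort(tr_spec, config.grid,
                                          baseline=config.baseline, id_prefix="tr-")
        log.append(f"simulated training cohort: {tr_spec.n_disease} disease / "
                   f"{tr_spec.n_healthy} healthy, seed={tr_spec.seed}")
    pre = preprocess_cohort(train_cohort, config.smoothing, config.normalization)
    log.append(f"preprocess: smooth fwhm={config.smoothing.fwhm_mm} mm then "
               f"normalize in-mask mean to {config.normalization.target_mean}")
    mask, statmap = build_mask(pre, p_voxel=config.p_voxel, k_min=config.k_min,
                               connectivity=config.connectivity)
    log.append(f"stage 1: p<{config.p_voxel} one-sided (healthy>disease), "
               f"{config.connectivity}-connectivity, k>={config.k_min}; "
               f"mask={mask.n_voxels} voxels in {len(mask.report)} clusters")
    if mask.n_voxels == 0:
        raise ValueError(
            "discriminative mask is empty after thresholding; consider a larger "
            "planted effect, a looser p_voxel, or a smaller k_min"
        )
    features = extract_features(pre, mask)
    model = train_linear_svm(features, C=config.C)
    model.mask_sha256 = mask_checksum(mask.mask)
    train_scores = decision_scores(model, features)
    log.append(f"stage 2: linear SVM C={config.C} on {features.X.shape[0]} x "
               f"{features.X.shape[1]} features; model checksum {model.checksum()[:12]}")
    return TrainingArtifacts(mask=mask, statmap=statmap, model=model,
                             train_ids=train_cohort.ids, train_scores=train_scores,
                             log=log)


def run_testing(config: RunConfig, artifacts: TrainingArtifacts,
                test_cohort: Cohort | None = None) -> RunReport:
    """Testing branch: apply the frozen mask and model to held-out subjects."""
    log = list(artifacts.log)
    _, te_spec = config.resolved_specs()
    if test_cohort is None:
        test_cohort, _ = generate_cohort(te_spec, config.grid,
                                         baseline=config.baseline, id_prefix="te-")
        log.append(f"simulated testing cohort: {te_spec.n_disease} disease / "
                   f"{te_spec.n_healthy} healthy, seed={te_spec.seed}")
    overlap = set(test_cohort.ids) & set(artifacts.train_ids)
    if overlap:
        raise ValueError(f"train/test leakage: shared subject ids {sorted(overlap)[:5]}")
    if tuple(test_cohort.grid.shape) != tuple(artifacts.mask.grid.shape):
        raise ValueError("testing grid does not match the training mask grid")
    pre = preprocess_cohort(test_cohort, config.smoothing, config.normalization)
    log.append("testing scans preprocessed with training-time parameters")
    features = extract_features(pre, artifacts.mask)
    scoreset = decision_scores(artifacts.model, features)
    cm = confusion(scoreset)
    mets = metrics(cm)
    u, p, method = score_separation(scoreset)
    log.append(f"scored {len(scoreset.subject_ids)} held-out subjects; "
               f"Mann-Whitney U={u:.1f} p={p:.4g} ({method})")
    from . import __version__

    return RunReport(
        config=config.echo(),
        version=__version__,
        cluster_report=artifacts.mask.report,
        model_checksum=artifacts.model.checksum(),
        cm=cm,
        metrics=mets,
        scores=scoreset.to_frame(),
        mann_whitney={"U": u, "p_two_sided": p, "method": method},
        log=log,
    )


def run_all(config: RunConfig) -> tuple[TrainingArtifacts, RunReport]:
    artifacts = run_training(config)
    report = run_testing(config, artifacts)
    return artifacts, report


def save_artifacts(artifacts: TrainingArtifacts, report: RunReport, out_dir) -> None:
    """Archive every intermediate so reported numbers are recomputable."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = artifacts.mask.grid
    save_volume(artifacts.statmap.t, grid, out / "tmap.nii.gz")
    save_volume(artifacts.mask.mask.astype(np.float32), grid, out / "mask.nii.gz")
    save_volume(artifacts.mask.labels.astype(np.float32), grid,
                out / "cluster_labels.nii.gz")
    save_volume(weight_map(artifacts.model, artifacts.mask, grid), grid,
                out / "weight_map.nii.gz")
    artifacts.mask.write_report(out / "cluster_report.tsv")
    artifacts.model.to_json(out / "model.json")
    report.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    report.save(out / "report.json")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(report.log) + "\n")
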