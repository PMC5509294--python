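"""Synthetic two-group FDG-PET cohorts with planted hypometabolic clusters.

The generator emulates spatially aligned brain volumes for a disease
group and a healthy group.  Each scan is a smooth ellipsoidal "brain" at
a baseline uptake level, with the disease group carrying fractional
intensity reductions inside configurable spherical clusters
(hypometabolism), an additive age-related intensity trend, a per-subject
multiplicative global-scaling factor, and additive Gaussian noise.
Because the planted clusters are known exactly, every downstream stage
(mask construction, decoding, evaluation) can be scored against ground
truth.

Noise model for a subject with scaling factor g ~ N(1, global_scale_sd)
truncated positive and voxel noise eps ~ N(0, noise_sd) inside the brain
mask::

    intensity = g * (template * (1 - effect * is_disease)
                     + age_slope * (age - reference_age)) + eps

and exactly zero outside the mask.  The disease effect is multiplicative
(a fractional reduction, matching hypometabolism semantics); the age
effect is additive in intensity units per year, centred on the pooled
mean age so the ANCOVA covariate is consequential but mean-neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, load_volume, save_volume

#: Hard truncation bounds for simulated ages (years).
AGE_BOUNDS = (18.0, 90.0)

#: Default template baseline uptake (arbitrary intensity units).
DEFAULT_BASELINE = 100.0


@dataclass(frozen=True)
class ClusterSpec:
    """A spherical region of group-level hypometabolism.

    effect_fraction is the fractional intensity reduction in the disease
    group (0.2 means disease voxels sit at 80% of the healthy level).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    effect_fraction: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError(f"radius_mm must be > 0, got {self.radius_mm}")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError(
                f"effect_fraction must be in [0, 1], got {self.effect_fraction}"
            )
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one simulated cohort.

    Default group sizes mirror the training cohort of the motivating
    study (100 disease / 44 healthy); ages are drawn per group from
    truncated normals with the study's means and SDs.
    """

    n_disease: int = 100
    n_healthy: int = 44
    age_mean_disease: float = 46.5
    age_sd_disease: float = 12.0
    age_mean_healthy: float = 45.4
    age_sd_healthy: float = 16.0
    age_slope: float = -0.15  # intensity units per year of age
    noise_sd: float = 10.0
    global_scale_sd: float = 0.05
    clusters: tuple[ClusterSpec, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_disease < 1 or self.n_healthy < 1:
            raise ValueError("both groups need at least one subject")
        if self.noise_sd < 0 or self.global_scale_sd < 0:
            raise ValueError("noise_sd and global_scale_sd must be >= 0")
        object.__setattr__(self, "clusters", tuple(self.clusters))

    @property
    def reference_age(self) -> float:
        """Pooled mean age used to centre the age trend."""
        n = self.n_disease + self.n_healthy
        return (
            self.n_disease * self.age_mean_disease
            + self.n_healthy * self.age_mean_healthy
        ) / n


@dataclass
class SubjectScan:
    id: str
    group: str  # "disease" | "healthy"
    age: float
    volume: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in ("disease", "healthy"):
            raise ValueError(f"group must be 'disease' or 'healthy', got {self.group!r}")
        if not np.all(np.isfinite(self.volume)):
            raise ValueError(f"subject {self.id}: volume contains non-finite values")


@dataclass
class Cohort:
    """A set of aligned subject scans sharing one grid and brain mask."""

    grid: GridSpec
    subjects: list[SubjectScan]
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")
        for s in self.subjects:
            if s.volume.shape != tuple(self.grid.shape):
                raise ValueError(f"subject {s.id} volume shape mismatch with grid")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        """+1 for disease, -1 for healthy, in subject order."""
        return np.array([1 if s.group == "disease" else -1 for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def data_matrix(self) -> np.ndarray:
        """Subjects x voxels matrix (flattened volumes, raster order)."""
        return np.stack([s.volume.ravel() for s in self.subjects])

    def manifest(self, paths: dict[str, str] | None = None) -> pd.DataFrame:
        paths = paths or {}
        return pd.DataFrame(
            {
                "subject_id": [s.id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "path": [paths.get(s.id, "") for s in self.subjects],
            }
        )


def make_template(grid: GridSpec, baseline: float = DEFAULT_BASELINE):
    """Ellipsoidal brain phantom at a constant baseline intensity.

    The ellipsoid is centred on the grid with semi-axes at 45% of each
    axis extent; voxels inside are set to ``baseline``, outside to 0.
    Returns ``(template, brain_mask)``.
    """
    if not baseline > 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    if any(s < 3 for s in grid.shape):
        raise ValueError(f"degenerate grid (axis < 3 voxels): {grid.shape}")
    center = (np.asarray(grid.shape, dtype=float) - 1.0) / 2.0
    semi = 0.45 * (np.asarray(grid.shape, dtype=float) - 1.0)
    ii, jj, kk = np.meshgrid(*[np.arange(s, dtype=float) for s in grid.shape],
                             indexing="ij", sparse=True)
    q = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    mask = q <= 1.0
    template = np.where(mask, float(baseline), 0.0)
    return template, mask


def effect_map(
    grid: GridSpec, brain_mask: np.ndarray, clusters: list[ClusterSpec] | tuple
) -> np.ndarray:
    """Per-voxel fractional reduction planted in the disease group.

    Overlapping spheres combine by max (never sum), so effects stay in
    [0, 1].  A cluster entirely outside the brain mask triggers a
    warning, not an error.
    """
    out = np.zeros(grid.shape, dtype=float)
    if not clusters:
        return out
    xx, yy, zz = grid.coordinate_grids()
    for c in clusters:
        d2 = (
            (xx - c.center_mm[0]) ** 2
            + (yy - c.center_mm[1]) ** 2
            + (zz - c.center_mm[2]) ** 2
        )
        sphere = d2 <= c.radius_mm**2
        inside = sphere & brain_mask
        if not inside.any():
            warnings.warn(
                f"cluster at {c.center_mm} r={c.radius_mm}mm lies entirely "
                "outside the brain mask",
                stacklevel=2,
            )
            continue
        np.maximum(out, np.where(inside, c.effect_fraction, 0.0), out=out)
    out[~brain_mask] = 0.0
    return out


def simulate_subject(
    template: np.ndarray,
    brain_mask: np.ndarray,
    effect: np.ndarray,
    group: str,
    age: float,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "s000",
) -> SubjectScan:
    """Draw one subject scan under the cohort noise model."""
    is_disease = 1.0 if group == "disease" else 0.0
    clean = template * (1.0 - effect * is_disease)
    signal = clean + spec.age_slope * (age - spec.reference_age)
    g = 1.0
    if spec.global_scale_sd > 0:
        g = 0.0
        while g <= 0.0:
            g = rng.normal(1.0, spec.global_scale_sd)
    vol = g * signal
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=template.shape)
    vol = np.where(brain_mask, vol, 0.0)
    return SubjectScan(id=subject_id, group=group, age=float(age), volume=vol)


def _truncated_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Normal(mean, sd) ages truncated to AGE_BOUNDS by resampling."""
    lo, hi = AGE_BOUNDS
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        ages[filled : filled + ok.size] = ok
        filled += ok.size
    return ages


def generate_cohort(
    spec: CohortSpec,
    grid: GridSpec,
    baseline: float = DEFAULT_BASELINE,
    id_prefix: str = "",
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full cohort plus its manifest.

    Randomness flows from ``spec.seed`` through named substreams (ages,
    then per-subject scale/noise) so runs are bit-reproducible; a missing
    seed is an error.  ``id_prefix`` keeps training and testing subject
    ids disjoint.
    """
    if spec.seed is None:
        raise ValueError("CohortSpec.seed is required for reproducible generation")
    template, brain_mask = make_template(grid, baseline)
    effect = effect_map(grid, brain_mask, spec.clusters)

    root = np.random.SeedSequence(spec.seed)
    age_seq, noise_seq = root.spawn(2)
    age_rng = np.random.default_rng(age_seq)
    noise_rng = np.random.default_rng(noise_seq)

    ages_d = _truncated_ages(age_rng, spec.n_disease, spec.age_mean_disease,
                             spec.age_sd_disease)
    ages_h = _truncated_ages(age_rng, spec.n_healthy, spec.age_mean_healthy,
                             spec.age_sd_healthy)

    subjects: list[SubjectScan] = []
    for i, age in enumerate(ages_d):
        sid = f"{id_prefix}d{i + 1:03d}"
        subjects.append(
            simulate_subject(template, brain_mask, effect, "disease", age, spec,
                             noise_rng, sid)
        )
    for i, age in enumerate(ages_h):
        sid = f"{id_prefix}h{i + 1:03d}"
        subjects.append(
            simulate_subject(template, brain_mask, effect, "healthy", age, spec,
                             noise_rng, sid)
        )
    cohort = Cohort(grid=grid, subjects=subjects, brain_mask=brain_mask)
    return cohort, cohort.manifest()


def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write each scan as NIfTI-1 plus a TSV manifest; returns the manifest."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for s in cohort.subjects:
        p = out_dir / f"{s.id}.nii.gz"
        save_volume(s.volume, cohort.grid, p)
        paths[s.id] = str(p)
    save_volume(cohort.brain_mask.astype(np.float32), cohort.grid,
                out_dir / "brain_mask.nii.gz")
    manifest = cohort.manifest(paths)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_cohort(in_dir) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    from pathlib import Path

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    mask_data, grid = load_volume(in_dir / "brain_mask.nii.gz")
    subjects = []
    for row in manifest.itertuples(index=False):
        vol, vgrid = load_volume(row.path)
        if vgrid.shape != grid.shape:
            raise ValueError(f"grid mismatch for subject {row.subject_id}")
        subjects.append(SubjectScan(id=str(row.subject_id), group=str(row.group),
                                    age=float(row.age), volume=vol))
    return Cohort(grid=grid, subjects=subjects, brain_mask=mask_data > 0.5)
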