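"""Stage 1 statistics: GLM t-map oracles, thresholds, cluster machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petmvpa import (
    Cohort,
    GridSpec,
    SubjectScan,
    apply_extent_threshold,
    build_design,
    fit_voxelwise_glm,
    label_clusters,
    threshold_voxels,
)
from petmvpa.glm import StatMap, build_mask

from conftest import random_cohort
from _oracles import flood_fill_components, pooled_two_sample_t


def tiny_cohort(values_disease, values_healthy, ages=None):
    """One-voxel cohort with prescribed values (and optional ages)."""
    shape = (1, 1, 1)
    grid = GridSpec(shape)
    subjects = []
    n = len(values_disease) + len(values_healthy)
    ages = ages if ages is not None else [50.0] * n
    i = 0
    for v in values_disease:
        subjects.append(SubjectScan(f"d{i}", "disease", ages[i], np.full(shape, float(v))))
        i += 1
    for v in values_healthy:
        subjects.append(SubjectScan(f"h{i}", "healthy", ages[i], np.full(shape, float(v))))
        i += 1
    return Cohort(grid=grid, subjects=subjects, brain_mask=np.ones(shape, dtype=bool))


class TestDesign:
    def test_single_group_rejected(self):
        c = tiny_cohort([1, 2, 3], [])
        # Cohort itself allows it; the design must refuse
        with pytest.raises(ValueError, match="both groups"):
            build_design(c)

    def test_constant_age_dropped_with_warning(self):
        c = tiny_cohort([1, 2, 3], [4, 5, 6], ages=[50.0] * 6)
        with pytest.warns(UserWarning, match="age is constant"):
            d = build_design(c)
        assert d.columns == ["group_healthy", "intercept"]
        assert d.rank == 2

    def test_design_shape_and_contrast(self):
        rng = np.random.default_rng(0)
        c = random_cohort(rng, 100, 44)
        d = build_design(c)
        assert d.X.shape == (144, 3)
        assert d.columns == ["group_healthy", "age_centered", "intercept"]
        # contrast touches only the group column
        assert d.contrast[0] == 1.0 and np.all(d.contrast[1:] == 0.0)


class TestVoxelwiseGLM:
    def test_reduces_to_pooled_two_sample_t(self):
        c = tiny_cohort([1, 2, 3], [4, 5, 6])
        with pytest.warns(UserWarning):
            d = build_design(c)  # constant age falls back to group + intercept
        sm = fit_voxelwise_glm(c, d)
        # closed form: healthy {4,5,6} minus disease {1,2,3}, pooled sd 1
        assert sm.t[0, 0, 0] == pytest.approx(3.0 * np.sqrt(1.5), abs=1e-10)
        assert sm.df == 4

    def test_identical_groups_give_t0_p_half(self):
        c = tiny_cohort([1, 2, 3], [1, 2, 3])
        with pytest.warns(UserWarning):
            d = build_design(c)
        sm = fit_voxelwise_glm(c, d)
        assert sm.t[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert sm.p[0, 0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_voxel_is_degenerate(self):
        c = tiny_cohort([0, 0, 0], [0, 0, 0])
        with pytest.warns(UserWarning):
            d = build_design(c)
        sm = fit_voxelwise_glm(c, d)
        assert sm.t[0, 0, 0] == 0.0
        assert sm.p[0, 0, 0] == 1.0

    def test_age_covariate_absorbs_age_driven_signal(self):
        # groups differ in age and voxel values follow age, not group:
        # the ANCOVA t for group must match the explicit matrix-algebra
        # oracle and be null-like, while the naive two-sample t is inflated
        rng = np.random.default_rng(3)
        ages = list(rng.uniform(55, 70, size=6)) + list(rng.uniform(30, 45, size=6))
        vals = [20.0 + 0.5 * a + rng.normal(0, 0.1) for a in ages]
        c = tiny_cohort(vals[:6], vals[6:], ages=ages)
        d = build_design(c)
        sm = fit_voxelwise_glm(c, d)
        # explicit matrix-algebra oracle for the same model
        healthy = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([healthy, np.asarray(ages) - np.mean(ages), np.ones(12)])
        y = np.asarray(vals)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (12 - 3)
        cvec = np.array([1.0, 0.0, 0.0])
        t_oracle = (cvec @ beta) / np.sqrt(s2 * cvec @ np.linalg.inv(X.T @ X) @ cvec)
        assert sm.t[0, 0, 0] == pytest.approx(t_oracle, abs=1e-8)
        assert abs(sm.t[0, 0, 0]) < 3.0
        # the age-confounded naive contrast is far larger in magnitude
        from _oracles import pooled_two_sample_t as naive_t

        t_naive, _ = naive_t(y[6:], y[:6])
        assert abs(t_naive) > 5 * abs(sm.t[0, 0, 0])

    def test_matches_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            c = random_cohort(rng, n_disease=int(rng.integers(3, 8)),
                              n_healthy=int(rng.integers(3, 8)), with_ages=False)
            with pytest.warns(UserWarning):
                d = build_design(c)
            sm = fit_voxelwise_glm(c, d)
            Y = c.data_matrix()
            labels = c.labels
            for v in range(0, Y.shape[1], 7):
                t_or, df_or = pooled_two_sample_t(Y[labels == -1, v], Y[labels == 1, v])
                assert sm.t.ravel()[v] == pytest.approx(t_or, abs=1e-8)
                assert sm.df == df_or


class TestThreshold:
    def test_strict_inequality_at_p_threshold(self):
        grid = GridSpec((1, 1, 3))
        df = 142
        t_crit = stats.t.isf(0.005, df)
        t = np.array([[[t_crit, t_crit + 1e-6, 0.0]]])
        p = stats.t.sf(t, df)
        sm = StatMap(t=t, df=df, p=p, z=stats.norm.isf(p), grid=grid)
        kept = threshold_voxels(sm, 0.005)
        assert not kept[0, 0, 0]   # p exactly 0.005 is excluded
        assert kept[0, 0, 1]       # just past the critical value is included
        assert not kept[0, 0, 2]


class TestLabelClusters:
    def test_face_adjacent_voxels_form_one_cluster(self):
        vol = np.zeros((5, 5, 5), dtype=bool)
        vol[1, 1, 1] = vol[1, 1, 2] = True
        lab = label_clusters(vol, connectivity=18)
        assert lab.max() == 1 and (lab > 0).sum() == 2

    def test_corner_sharing_voxels_split_under_18(self):
        vol = np.zeros((5, 5, 5), dtype=bool)
        vol[1, 1, 1] = vol[2, 2, 2] = True  # share only a corner
        assert label_clusters(vol, connectivity=18).max() == 2
        assert label_clusters(vol, connectivity=26).max() == 1

    def test_empty_volume_has_zero_clusters(self):
        assert label_clusters(np.zeros((4, 4, 4), dtype=bool)).max() == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(10):
            vol = rng.random((16, 16, 16)) < 0.2
            lab = label_clusters(vol, connectivity)
            got = [set(zip(*np.nonzero(lab == i))) for i in range(1, lab.max() + 1)]
            expected = flood_fill_components(vol, connectivity)
            assert sorted(map(frozenset, got)) == sorted(map(frozenset, expected))

    def test_labels_deterministic_raster_order(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[3, 3, 3] = True
        vol[0, 0, 0] = True
        lab = label_clusters(vol)
        assert lab[0, 0, 0] == 1 and lab[3, 3, 3] == 2


class TestExtentThreshold:
    def _statmap_for(self, binary, grid):
        t = binary.astype(float)
        p = np.where(binary, 1e-4, 0.5)
        return StatMap(t=t, df=50, p=p, z=stats.norm.isf(p), grid=grid)

    def test_extent_bound_is_inclusive(self):
        grid = GridSpec((10, 10, 10))
        vol = np.zeros(grid.shape, dtype=bool)
        vol.ravel()[:199] = True  # a single compact run of 199 voxels
        lab = label_clusters(vol, 6)
        with pytest.warns(UserWarning, match="no cluster survived"):
            cm = apply_extent_threshold(lab, self._statmap_for(vol, grid), k_min=200)
        assert cm.n_voxels == 0
        vol.ravel()[:200] = True
        lab = label_clusters(vol, 6)
        cm = apply_extent_threshold(lab, self._statmap_for(vol, grid), k_min=200)
        assert cm.n_voxels == 200

    def test_report_sorted_by_descending_size(self):
        grid = GridSpec((12, 12, 12))
        vol = np.zeros(grid.shape, dtype=bool)
        vol[0:2, 0:2, 0:2] = True       # 8 voxels
        vol[6:10, 6:10, 6:10] = True    # 64 voxels
        lab = label_clusters(vol, 18)
        cm = apply_extent_threshold(lab, self._statmap_for(vol, grid), k_min=5)
        assert list(cm.report["K"]) == [64, 8]
        assert list(cm.report["cluster_id"]) == [1, 2]

    def test_peak_location_and_value(self):
        grid = GridSpec((8, 8, 8), voxel_size_mm=2.0)
        vol = np.zeros(grid.shape, dtype=bool)
        vol[2:5, 2:5, 2:5] = True
        t = np.zeros(grid.shape)
        t[vol] = 1.0
        t[3, 4, 2] = 9.0
        p = np.where(vol, 1e-4, 0.5)
        sm = StatMap(t=t, df=50, p=p, z=stats.norm.isf(p), grid=grid)
        cm = apply_extent_threshold(label_clusters(vol), sm, k_min=1)
        row = cm.report.iloc[0]
        assert row["peak_t"] == 9.0
        assert (row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"]) == (6.0, 8.0, 4.0)

    def test_empty_mask_warns(self):
        grid = GridSpec((6, 6, 6))
        vol = np.zeros(grid.shape, dtype=bool)
        vol[0, 0, 0] = True
        lab = label_clusters(vol)
        with pytest.warns(UserWarning, match="no cluster survived"):
            cm = apply_extent_threshold(lab, self._statmap_for(vol, grid), k_min=200)
        assert cm.n_voxels == 0 and cm.report.empty


class TestMaskMonotonicity:
    def test_tighter_thresholds_never_grow_the_mask(self):
        rng = np.random.default_rng(21)
        c = random_cohort(rng, 12, 12, shape=(8, 9, 8))
        mask_loose, _ = build_mask(c, p_voxel=0.2, k_min=2)
        mask_p, _ = build_mask(c, p_voxel=0.05, k_min=2)
        mask_k, _ = build_mask(c, p_voxel=0.2, k_min=10)
        assert not (mask_p.mask & ~mask_loose.mask).any()
        assert not (mask_k.mask & ~mask_loose.mask).any()
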