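import numpy as np
import pytest
from scipy import ndimage

from corticovar import synthetic
from corticovar.core_stats import two_sample_t
from corticovar.fc import (
    FcZMap,
    extract_sphere_roi,
    friston24_expand,
    group_fc_inference,
    preprocess_bold,
    subject_fc_zmap,
)


class TestFriston24:
    def test_zero_motion_gives_zero_columns(self):
        out = friston24_expand(np.zeros((50, 6)))
        assert out.shape == (50, 24)
        assert np.all(out == 0)

    def test_lag_block_definition(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((30, 6))
        out = friston24_expand(m)
        assert np.array_equal(out[1:, 12:18], m[:-1])
        assert np.all(out[0, 12:] == 0)
        assert np.array_equal(out[:, 6:12], m ** 2)

    def test_wrong_column_count(self):
        with pytest.raises(ValueError):
            friston24_expand(np.zeros((30, 5)))


class TestPreprocess:
    def test_discard_shortens_run(self, bold_cohort):
        pre = preprocess_bold(bold_cohort[0], discard=10)
        assert pre.n_volumes == 190

    def test_full_length_run_keeps_230(self):
        meta = synthetic.make_cohort_meta(1, 0, seed=0)
        run = synthetic.simulate_bold_cohort(meta, grid=(6, 6, 6),
                                             n_volumes=240, seed=0)[0]
        assert preprocess_bold(run).n_volumes == 230

    def test_residuals_orthogonal_to_design(self, bold_cohort):
        from corticovar.fc import _nuisance_design

        pre = preprocess_bold(bold_cohort[0], discard=10, smooth_fwhm=0.0)
        X, _ = _nuisance_design(pre, global_signal=True)
        Y = pre.data.reshape(-1, pre.n_volumes).T
        Xn = X / np.linalg.norm(X, axis=0, keepdims=True)
        Yn = Y / np.maximum(np.linalg.norm(Y, axis=0, keepdims=True), 1e-12)
        assert np.abs(Xn.T @ Yn).max() < 1e-8

    def test_pure_trend_voxel_removed(self):
        meta = synthetic.make_cohort_meta(1, 0, seed=1)
        run = synthetic.simulate_bold_cohort(meta, grid=(6, 6, 6),
                                             n_volumes=80, noise_sd=1.0,
                                             seed=1)[0]
        run.data[0, 0, 0] = np.linspace(0, 5, 80)
        pre = preprocess_bold(run, discard=0, smooth_fwhm=0.0)
        assert np.abs(pre.data[0, 0, 0]).max() < 1e-8

    def test_idempotent_residualization(self, bold_cohort):
        once = preprocess_bold(bold_cohort[0], discard=0, smooth_fwhm=0.0)
        twice = preprocess_bold(once, discard=0, smooth_fwhm=0.0)
        assert np.abs(twice.data - once.data).max() < 1e-8 * \
            np.abs(once.data).max()

    def test_too_short_after_discard(self):
        meta = synthetic.make_cohort_meta(1, 0, seed=2)
        run = synthetic.simulate_bold_cohort(meta, grid=(6, 6, 6),
                                             n_volumes=25, seed=2)[0]
        with pytest.raises(ValueError):
            preprocess_bold(run, discard=10)


class TestSphereRoi:
    def test_seven_voxels_on_3mm_grid(self, bold_cohort):
        run = bold_cohort[0]
        center = run.voxel_to_world([[6, 7, 6]])[0]
        # count by replacing data with voxel-id field
        marked = run.data.copy()
        series = extract_sphere_roi(run, center, radius=3.0)
        # center + 6 face neighbours at exactly 3.0 mm
        flat = run.data.reshape(-1, run.n_volumes)
        ijk = np.indices(run.data.shape[:3]).reshape(3, -1).T
        world = run.voxel_to_world(ijk)
        d = np.linalg.norm(world - center, axis=1)
        assert (d <= 3.0 + 1e-9).sum() == 7
        expected = flat[d <= 3.0 + 1e-9].mean(axis=0)
        assert np.allclose(series, expected)

    def test_constant_field_gives_constant_series(self, bold_cohort):
        run = bold_cohort[0]
        orig = run.data
        run.data = np.ones_like(orig)
        try:
            series = extract_sphere_roi(run, (0.0, 0.0, 0.0), 3.0)
            assert np.allclose(series, 1.0)
        finally:
            run.data = orig

    def test_zero_radius_single_voxel(self, bold_cohort):
        run = bold_cohort[0]
        center = run.voxel_to_world([[6, 7, 6]])[0]
        series = extract_sphere_roi(run, center, radius=0.0)
        assert np.allclose(series, run.data[6, 7, 6])

    def test_outside_mask_reports_nearest(self, bold_cohort):
        run = bold_cohort[0]
        with pytest.raises(ValueError, match="nearest"):
            extract_sphere_roi(run, (500.0, 500.0, 500.0), 3.0)


class TestZMap:
    def test_seed_voxel_clipped_z(self, bold_cohort):
        run = preprocess_bold(bold_cohort[0], smooth_fwhm=0.0)
        series = run.data[6, 7, 6]
        zm = subject_fc_zmap(run, series)
        assert zm.z[6, 7, 6] == pytest.approx(np.arctanh(1 - 1e-7), rel=1e-6)

    def test_matches_kernel_composition(self, bold_cohort):
        from corticovar.core_stats import fisher_z, pearson_r

        run = preprocess_bold(bold_cohort[0], smooth_fwhm=0.0)
        series = extract_sphere_roi(run, (0.0, 0.0, 0.0), 3.0)
        zm = subject_fc_zmap(run, series)
        for ijk in [(0, 0, 0), (5, 5, 5), (11, 13, 11)]:
            r = pearson_r(run.data[ijk], series).r
            assert zm.z[ijk] == pytest.approx(fisher_z(r, clip=True),
                                              abs=1e-10)

    def test_null_voxels_center_on_zero(self):
        rng = np.random.default_rng(0)
        meta = synthetic.make_cohort_meta(1, 0, seed=3)
        run = synthetic.simulate_bold_cohort(
            meta, grid=(8, 8, 8), n_volumes=200, drift_slope=0.0,
            nuisance_amp=0.0, connectivity={"patient": np.zeros((1, 1)),
                                            "control": np.zeros((1, 1))},
            seed=3)[0]
        series = rng.standard_normal(200)
        zm = subject_fc_zmap(run, series)
        assert abs(np.nanmean(zm.z)) < 0.02

    def test_fisher_variance_stabilization(self):
        # var of null z over voxels ~ 1/(T-3)
        meta = synthetic.make_cohort_meta(1, 0, seed=4)
        run = synthetic.simulate_bold_cohort(
            meta, grid=(10, 10, 10), n_volumes=200, drift_slope=0.0,
            nuisance_amp=0.0, connectivity={"patient": np.zeros((1, 1)),
                                            "control": np.zeros((1, 1))},
            seed=4)[0]
        series = np.random.default_rng(5).standard_normal(200)
        zm = subject_fc_zmap(run, series)
        assert np.nanvar(zm.z) == pytest.approx(1 / (200 - 3), rel=0.10)


def _smooth_zmaps(rng, n, grid=(12, 12, 12), effect=0.0, ball=None):
    maps = []
    for _ in range(n):
        f = ndimage.gaussian_filter(rng.standard_normal(grid), 1.0,
                                    mode="wrap")
        f /= f.std()
        f *= 1.0 / np.sqrt(197)
        if ball is not None:
            f = f + effect * ball
        maps.append(FcZMap(subject_id="s", roi="seed", z=f))
    return maps


class TestGroupInference:
    def test_identical_groups_no_clusters(self):
        rng = np.random.default_rng(6)
        maps = _smooth_zmaps(rng, 6)
        base = [FcZMap(m.subject_id, m.roi, m.z + 0.5) for m in maps]
        dup = [FcZMap(m.subject_id, m.roi, m.z.copy()) for m in base]
        mask = np.ones((12, 12, 12), bool)
        res = group_fc_inference(base, dup, mask, np.diag([3, 3, 3, 1.0]))
        assert res.clusters == []

    def test_two_sample_map_matches_kernel(self, bold_cohort):
        pats = [r for r in bold_cohort if r.subject.group == "patient"][:5]
        ctls = [r for r in bold_cohort if r.subject.group == "control"][:5]
        zp, zc = [], []
        for run in pats + ctls:
            pre = preprocess_bold(run)
            series = extract_sphere_roi(
                pre, synthetic.default_roi_centers()[0], 3.0)
            zm = subject_fc_zmap(pre, series)
            (zp if run.subject.group == "patient" else zc).append(zm)
        res = group_fc_inference(zp, zc, bold_cohort[0].mask,
                                 bold_cohort[0].affine)
        sig = np.argwhere(res.significance_mask)[:5]
        for v in sig:
            a = [m.z[tuple(v)] for m in zp]
            b = [m.z[tuple(v)] for m in zc]
            t, _, _ = two_sample_t(a, b)
            assert res.t_twosample[tuple(v)] == pytest.approx(t, abs=1e-10)

    def test_empty_mask_warns_and_returns_empty(self):
        rng = np.random.default_rng(7)
        # tiny maps with no real connectivity: nothing passes mask_alpha
        maps_a = _smooth_zmaps(rng, 5)
        maps_b = _smooth_zmaps(rng, 5)
        mask = np.ones((12, 12, 12), bool)
        res = group_fc_inference(maps_a, maps_b, mask,
                                 np.diag([3, 3, 3, 1.0]), mask_alpha=1e-12)
        assert res.clusters == []
        assert not res.significance_mask.any()

    def test_null_family_wise_rate_controlled(self):
        rng = np.random.default_rng(8)
        mask = np.ones((12, 12, 12), bool)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        idx = np.indices((12, 12, 12)).reshape(3, -1).T
        ball = (np.linalg.norm(idx - 6, axis=1) < 3).reshape(12, 12, 12)
        fp = 0
        reps = 60
        for _ in range(reps):
            # both groups share the same true connectivity pattern
            zp = _smooth_zmaps(rng, 11, effect=0.4, ball=ball)
            zc = _smooth_zmaps(rng, 15, effect=0.4, ball=ball)
            res = group_fc_inference(zp, zc, mask, affine)
            fp += bool(res.clusters)
        assert fp / reps <= 0.10

    def test_stricter_voxel_alpha_never_adds_clusters(self, bold_cohort):
        zp, zc = [], []
        for run in bold_cohort:
            pre = preprocess_bold(run)
            series = extract_sphere_roi(
                pre, synthetic.default_roi_centers()[0], 3.0)
            zm = subject_fc_zmap(pre, series)
            (zp if run.subject.group == "patient" else zc).append(zm)
        loose = group_fc_inference(zp, zc, bold_cohort[0].mask,
                                   bold_cohort[0].affine, voxel_alpha=0.001)
        tight = group_fc_inference(zp, zc, bold_cohort[0].mask,
                                   bold_cohort[0].affine, voxel_alpha=0.0001)
        assert len(tight.clusters) <= len(loose.clusters)
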