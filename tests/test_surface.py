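import numpy as np
import pytest

from corticovar import synthetic
from corticovar.datatypes import SurfaceMesh
from corticovar.surface import (
    cluster_report,
    find_surface_clusters,
    smooth_surface,
    vertex_group_glm,
    VertexStatMap,
)


class TestSmoothing:
    def test_constant_field_preserved(self, small_mesh):
        c = np.full(small_mesh.n_vertices, 2.7)
        assert np.allclose(smooth_surface(small_mesh, c, 10.0), 2.7,
                           atol=1e-10)

    def test_zero_fwhm_is_identity(self, small_mesh):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(small_mesh.n_vertices)
        assert np.array_equal(smooth_surface(small_mesh, v, 0.0), v)

    def test_impulse_width_matches_requested_fwhm(self):
        mesh = synthetic.make_toy_surface(4, 50.0)
        imp = np.zeros(mesh.n_vertices)
        imp[0] = 1.0
        sm = smooth_surface(mesh, imp, 10.0)
        d = np.linalg.norm(mesh.vertices - mesh.vertices[0], axis=1)
        half = sm.max() / 2
        # interpolate the half-maximum crossing of the radial profile
        bins = np.linspace(0, 25, 100)
        idx = np.digitize(d, bins)
        prof, centers = [], []
        for i in range(1, len(bins)):
            sel = idx == i
            if sel.any():
                prof.append(sm[sel].mean())
                centers.append(d[sel].mean())
        prof, centers = np.array(prof), np.array(centers)
        k = np.argmax(prof < half)
        x0, x1 = centers[k - 1], centers[k]
        y0, y1 = prof[k - 1], prof[k]
        r_half = x0 + (half - y0) / (y1 - y0) * (x1 - x0)
        assert 2 * r_half == pytest.approx(10.0, rel=0.20)

    def test_stack_matches_single(self, small_mesh):
        rng = np.random.default_rng(1)
        V = rng.standard_normal((3, small_mesh.n_vertices))
        stacked = smooth_surface(small_mesh, V, 8.0)
        single = np.stack([smooth_surface(small_mesh, v, 8.0) for v in V])
        assert np.allclose(stacked, single, atol=1e-12)


class TestVertexGlm:
    def test_null_p_values_uniform(self, small_mesh):
        # no group effect, unsmoothed noise: vertexwise p ~ U(0,1)
        meta = synthetic.make_cohort_meta(12, 12, seed=2)
        ds = synthetic.simulate_thickness_dataset(
            small_mesh, meta, noise_sd=0.15, smoothness_fwhm=0.0, seed=3)
        stats = vertex_group_glm(ds, fwhm=0.0)
        p = np.sort(stats.p)
        grid = (np.arange(len(p)) + 0.5) / len(p)
        ks = np.abs(p - grid).max()
        assert ks < 0.05

    def test_injected_patch_reaches_significance(self, thickness_dataset):
        stats = vertex_group_glm(thickness_dataset, fwhm=10.0)
        assert stats.p[thickness_dataset.injected_patch].min() < 0.001

    def test_matches_core_glm_per_vertex(self, thickness_dataset):
        from corticovar.core_stats import ols_glm
        from corticovar.surface import _design_matrix

        stats = vertex_group_glm(thickness_dataset, fwhm=10.0)
        Y = smooth_surface(thickness_dataset.mesh,
                           thickness_dataset.thickness, 10.0)
        X, contrast, _ = _design_matrix(thickness_dataset)
        for v in (0, 57, 300):
            fit = ols_glm(Y[:, v], X, contrast)
            assert stats.t[v] == pytest.approx(fit.contrast_t[0], abs=1e-10)

    def test_too_few_subjects_rejected(self, small_mesh):
        meta = synthetic.make_cohort_meta(2, 5, seed=0)
        ds = synthetic.simulate_thickness_dataset(small_mesh, meta, seed=0)
        with pytest.raises(ValueError):
            vertex_group_glm(ds)


def _flat_strip_mesh(n=10, spacing=3.0):
    """Planar strip of 2*(n-1) triangles with easily computed areas."""
    verts = []
    for i in range(n):
        verts.append([i * spacing, 0.0, 0.0])
        verts.append([i * spacing, spacing, 0.0])
    tris = []
    for i in range(n - 1):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        tris.append([a, b, c])
        tris.append([b, d, c])
    return SurfaceMesh(vertices=np.array(verts), triangles=np.array(tris))


class TestClusters:
    def _stat_map(self, mesh, pvals, signs):
        t = np.where(np.asarray(pvals) < 1, 5.0, 0.0) * np.asarray(signs)
        return VertexStatMap(mesh=mesh, t=t, p=np.asarray(pvals, float),
                             sign=np.asarray(signs, int), df=10)

    def test_no_suprathreshold_vertices(self, small_mesh):
        n = small_mesh.n_vertices
        sm = self._stat_map(small_mesh, np.ones(n), np.zeros(n))
        assert find_surface_clusters(sm) == []

    def test_small_cluster_discarded(self):
        mesh = synthetic.make_toy_surface(4, 50.0)
        n = mesh.n_vertices
        p = np.ones(n)
        s = np.zeros(n, int)
        p[0], s[0] = 1e-5, 1
        sm = self._stat_map(mesh, p, s)
        # a single vertex's area on this finer mesh is well under 30 mm^2
        assert mesh.vertex_area[0] < 30
        assert find_surface_clusters(sm, min_area=30) == []

    def test_hand_built_patch_extent(self):
        mesh = _flat_strip_mesh()
        members = np.array([4, 5, 6, 7])       # interior quad pair
        p = np.ones(mesh.n_vertices)
        s = np.zeros(mesh.n_vertices, int)
        p[members], s[members] = 1e-5, 1
        sm = self._stat_map(mesh, p, s)
        clusters = find_surface_clusters(sm, min_area=1.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == sorted(members)
        assert clusters[0].extent == pytest.approx(
            mesh.vertex_area[members].sum())

    def test_sign_homogeneous_clusters_never_merge(self):
        mesh = _flat_strip_mesh()
        p = np.full(mesh.n_vertices, 1e-5)
        s = np.ones(mesh.n_vertices, int)
        s[mesh.vertices[:, 0] > 12] = -1
        t = 5.0 * s
        sm = VertexStatMap(mesh=mesh, t=t, p=p, sign=s, df=10)
        clusters = find_surface_clusters(sm, min_area=0.0)
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}

    def test_extent_invariant_to_vertex_relabeling(self, small_mesh):
        rng = np.random.default_rng(4)
        n = small_mesh.n_vertices
        p = rng.uniform(size=n) * 0.02
        s = np.ones(n, int)
        sm = self._stat_map(small_mesh, p, s)
        base = sorted(c.extent for c in find_surface_clusters(sm, 0.01, 0.0))
        perm = rng.permutation(n)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        mesh2 = SurfaceMesh(vertices=small_mesh.vertices[perm],
                            triangles=inv[small_mesh.triangles])
        sm2 = self._stat_map(mesh2, p[perm], s[perm])
        other = sorted(c.extent for c in find_surface_clusters(sm2, 0.01, 0.0))
        assert np.allclose(base, other)

    def test_stricter_threshold_shrinks_total_area(self, small_mesh):
        rng = np.random.default_rng(5)
        n = small_mesh.n_vertices
        p = rng.uniform(size=n) * 0.05
        s = np.ones(n, int)
        sm = self._stat_map(small_mesh, p, s)
        loose = sum(c.extent for c in find_surface_clusters(sm, 0.02, 0.0))
        tight = sum(c.extent for c in find_surface_clusters(sm, 0.005, 0.0))
        assert tight <= loose

    def test_null_cluster_count_baseline(self, small_mesh):
        # regression guard: spurious >=30 mm^2 clusters are rare under null
        counts = []
        for seed in range(10):
            meta = synthetic.make_cohort_meta(11, 24, seed=seed)
            ds = synthetic.simulate_thickness_dataset(small_mesh, meta,
                                                      noise_sd=0.15,
                                                      seed=200 + seed)
            stats = vertex_group_glm(ds, fwhm=10.0)
            counts.append(len(find_surface_clusters(stats)))
        assert np.mean(counts) <= 2.0


class TestClusterReport:
    def test_columns_match_reference_table(self, thickness_dataset):
        stats = vertex_group_glm(thickness_dataset, fwhm=10.0)
        clusters = find_surface_clusters(stats)
        rep = cluster_report(clusters, thickness_dataset)
        assert list(rep.columns) == ["area", "peak_mni", "size_mm2",
                                     "p_value", "patient_mean_sd",
                                     "control_mean_sd"]
        assert len(rep) == len(clusters)

    def test_constant_thickness_summaries(self, small_mesh):
        meta = synthetic.make_cohort_meta(5, 5, seed=0)
        ds = synthetic.simulate_thickness_dataset(
            small_mesh, meta, noise_sd=0.0, age_slope=0.0, sex_shift=0.0,
            baseline=2.5, seed=0)
        from corticovar.datatypes import ClusterRecord
        cl = ClusterRecord(peak_index=0, peak_world=(0, 0, 0), extent=40.0,
                           peak_p=1e-4, sign=1, members=np.array([0]))
        rep = cluster_report([cl], ds)
        assert rep.loc[0, "patient_mean_sd"] == "2.50 (0.00)"
        assert rep.loc[0, "control_mean_sd"] == "2.50 (0.00)"
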