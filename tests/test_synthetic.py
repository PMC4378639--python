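"""Generators: geometric fidelity, statistical calibration, determinism."""

import math

import numpy as np
import pytest

from laminametrics import morphometry as mor
from laminametrics import proliferation as pro
from laminametrics import synthetic as syn


class TestOutlines:
    def test_degenerate_ellipse_is_circle(self):
        outline = syn.gen_outline(syn.OutlineSpec(2.0, 2.0, n_vertices=512))
        r = np.hypot(*outline.vertices.T)
        assert r == pytest.approx(np.ones_like(r))

    def test_ellipse_area_matches_closed_form(self):
        outline = syn.gen_outline(syn.OutlineSpec(12.8, 9.0, n_vertices=512))
        assert outline.polygon.area == pytest.approx(math.pi * 6.4 * 4.5, rel=0.005)

    def test_extents_exact_without_roughness(self):
        m = mor.measure_outline(syn.gen_outline(syn.OutlineSpec(14.2, 16.2)), axis="x")
        assert m.length == pytest.approx(14.2, rel=0.005)
        assert m.width == pytest.approx(16.2, rel=0.005)

    def test_seed_determinism(self):
        spec = syn.OutlineSpec(14.2, 16.2, roughness=0.1, seed=42)
        a = syn.gen_outline(spec).vertices
        b = syn.gen_outline(spec).vertices
        np.testing.assert_array_equal(a, b)

    def test_rough_outline_is_simple(self):
        for seed in range(5):
            syn.gen_outline(syn.OutlineSpec(10, 8, roughness=0.2, seed=seed)).validate()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            syn.OutlineSpec(-1, 2)
        with pytest.raises(ValueError):
            syn.OutlineSpec(1, 2, n_vertices=8)
        with pytest.raises(ValueError):
            syn.OutlineSpec(1, 2, roughness=-0.1)


class TestSurfaces:
    def test_flat_disc_plane_and_area(self):
        mesh = syn.gen_surface(syn.SurfaceSpec("flat_disc", 1.0, mesh_resolution=0.05))
        assert np.all(mesh.vertices[:, 2] == 0)

    def test_cap_vertices_on_sphere(self):
        mesh = syn.gen_surface(
            syn.SurfaceSpec("spherical_cap", 2.0, curvature_param=1.0, mesh_resolution=0.05)
        )
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert r == pytest.approx(np.full_like(r, 2.0))

    def test_single_boundary_loop(self):
        from laminametrics.geometry import boundary_loops

        for kind in ("flat_disc", "spherical_cap", "saddle"):
            mesh = syn.gen_surface(syn.SurfaceSpec(kind, 1.0, curvature_param=1.0,
                                                   mesh_resolution=0.08))
            assert len(boundary_loops(mesh.faces)) == 1

    def test_saddle_rim_longer_than_flat_rim(self):
        from laminametrics.geometry import mesh_metrics

        mesh = syn.gen_surface(syn.SurfaceSpec("saddle", 1.0, curvature_param=1.0,
                                               mesh_resolution=0.05))
        assert mesh_metrics(mesh).boundary_perimeter > 2 * math.pi


class TestCellMaps:
    def test_cell_count_tracks_area_budget(self):
        cmap = syn.gen_cell_map(1.0, 1.0, 10000.0, seed=1)
        assert 90 <= cmap.n_cells <= 110  # 1 mm^2 / 10^4 um^2 = 100

    def test_mean_area_within_ten_percent_of_target(self):
        for target in (160.0, 6000.0):
            cmap = syn.gen_cell_map(1.0, 0.5, target, seed=2)
            assert cmap.cells.area_um2.mean() == pytest.approx(target, rel=0.10)

    def test_tessellation_is_space_filling(self):
        cmap = syn.gen_cell_map(0.5, 0.5, 2000.0, seed=3)
        assert cmap.cells.area_um2.sum() == pytest.approx(500.0 * 500.0, rel=1e-6)

    def test_seed_determinism(self):
        a = syn.gen_cell_map(0.5, 0.2, 500.0, seed=9)
        b = syn.gen_cell_map(0.5, 0.2, 500.0, seed=9)
        np.testing.assert_array_equal(a.cells.to_numpy(), b.cells.to_numpy())

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_cell_map(-1.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            syn.gen_cell_map(1.0, 1.0, 0.0)


class TestFrontModels:
    def test_presets_hit_published_endpoint_values(self):
        col0 = syn.FRONT_PRESETS["col0_like"]
        assert float(col0(np.array(0.0))) == pytest.approx(0.25)
        assert float(col0(np.array(1.0))) == pytest.approx(0.10)
        tni = syn.FRONT_PRESETS["tni_like"]
        assert float(tni(np.array(0.0))) == pytest.approx(0.27)
        assert float(np.max(tni(np.linspace(0, 1, 101)))) == pytest.approx(0.40)
        assert float(tni(np.array(1.0))) == pytest.approx(0.15)
        jaw = syn.FRONT_PRESETS["jawD_like"]
        p = jaw(np.linspace(0, 1, 51))
        assert np.all(np.diff(p) >= 0)  # monotone increasing toward margin

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            syn.FrontModel(lambda x: 1.5 * np.ones_like(x))

    def test_assign_all_or_none(self):
        cmap = syn.gen_cell_map(0.4, 0.1, 200.0, seed=5)
        ones = syn.assign_gus(cmap, syn.FrontModel(lambda x: np.ones_like(x)), seed=0)
        assert ones.cells.gus.all()
        zeros = syn.assign_gus(cmap, syn.FrontModel(lambda x: np.zeros_like(x)), seed=0)
        assert not zeros.cells.gus.any()

    def test_bernoulli_calibration_at_constant_probability(self):
        # 10^4 cells at p = 0.25: fraction within 3 binomial SEs
        cmap = syn.gen_cell_map(2.0, 0.8, 160.0, seed=6)
        assert cmap.n_cells > 9000
        out = syn.assign_gus(cmap, syn.FrontModel(lambda x: np.full_like(x, 0.25)), seed=7)
        se = math.sqrt(0.25 * 0.75 / out.n_cells)
        assert out.cells.gus.mean() == pytest.approx(0.25, abs=3 * se)

    def test_assignment_determinism(self):
        cmap = syn.gen_cell_map(0.4, 0.1, 200.0, seed=5)
        a = syn.assign_gus(cmap, syn.FRONT_PRESETS["col0_like"], seed=11)
        b = syn.assign_gus(cmap, syn.FRONT_PRESETS["col0_like"], seed=11)
        assert (a.cells.gus == b.cells.gus).all()


class TestRenderedImages:
    def test_no_stained_cells_empty_mask(self):
        cmap = syn.gen_cell_map(0.3, 0.1, 300.0, seed=1)
        _, mask = syn.render_gus_image(cmap)
        assert not mask.any()

    def test_component_count_matches_stained_cells(self):
        from skimage import measure

        cmap = syn.gen_cell_map(0.5, 0.2, 300.0, seed=2)
        idx = cmap.cells.sample(n=50, random_state=0).index
        cmap.cells.loc[idx, "gus"] = True
        _, mask = syn.render_gus_image(cmap, pixel_size_um=1.0)
        assert measure.label(mask, connectivity=2).max() == 50

    def test_render_determinism(self):
        cmap = syn.gen_cell_map(0.3, 0.1, 300.0, seed=3)
        cmap = syn.assign_gus(cmap, syn.FRONT_PRESETS["col0_like"], seed=4)
        img1, _ = syn.render_gus_image(cmap, noise_sd=0.05, seed=8)
        img2, _ = syn.render_gus_image(cmap, noise_sd=0.05, seed=8)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)


class TestGrowthSeries:
    def test_peak_finite_difference_rate_matches_r_max(self):
        series = syn.gen_growth_series(syn.GrowthSpec(w_max=9.0, r_max=0.5, t_mid=8.0))
        fd = np.diff(series.width) / np.diff(series.day)
        assert fd.max() == pytest.approx(0.5, rel=0.05)

    def test_mutant_preset_peaks_at_twice_wild_type(self):
        assert syn.GROWTH_PRESETS["tni"].r_max == pytest.approx(
            2 * syn.GROWTH_PRESETS["col0"].r_max
        )

    def test_asymptote(self):
        spec = syn.GrowthSpec(w_max=9.0, r_max=0.5, t_mid=8.0)
        assert float(syn.logistic_width(np.array(1e6), spec)) == pytest.approx(9.0)

    def test_noise_reproducible(self):
        spec = syn.GrowthSpec(w_max=9.0, r_max=0.5, t_mid=8.0, noise_sd=0.3, seed=21)
        np.testing.assert_array_equal(
            syn.gen_growth_series(spec).width, syn.gen_growth_series(spec).width
        )


class TestZoneSeries:
    def test_noiseless_series_refits_exactly(self):
        spec = syn.ZoneSeriesSpec(slope=-0.37, intercept=1.25, noise_sd=0.0, seed=0)
        slope, r2 = pro.zone_slope(syn.gen_zone_series(spec))
        assert slope == pytest.approx(-0.37)
        assert r2 == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        spec = syn.ZoneSeriesSpec(slope=0.2, intercept=0.1, n_leaves=2, noise_sd=0.05, seed=3)
        _, r2 = pro.zone_slope(syn.gen_zone_series(spec))
        assert r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("preset", ["col0", "tni"])
    def test_preset_recovery_within_tolerance(self, preset):
        spec = syn.ZONE_PRESETS[preset]
        slope, r2 = pro.zone_slope(syn.gen_zone_series(spec))
        assert slope == pytest.approx(spec.slope, abs=0.10)
        assert 0.4 < r2 < 1.0

    def test_negative_zones_clipped_and_flagged(self):
        spec = syn.ZoneSeriesSpec(slope=-1.0, intercept=0.5, n_leaves=50,
                                  leaf_length_range=(1.0, 3.0), noise_sd=0.1, seed=1)
        records = syn.gen_zone_series(spec)
        assert all(r.zone_length >= 0 for r in records)
        assert any(r.clipped for r in records)


class TestTextIO:
    def test_outline_roundtrip(self, tmp_path):
        outline = syn.gen_outline(syn.OutlineSpec(5, 4, roughness=0.05, seed=1))
        path = tmp_path / "outline.csv"
        syn.save_outline_csv(outline, path)
        back = syn.load_outline_csv(path)
        np.testing.assert_allclose(back.vertices, outline.vertices, rtol=1e-12)

    def test_mesh_off_roundtrip(self, tmp_path):
        mesh = syn.gen_surface(syn.SurfaceSpec("saddle", 1.0, mesh_resolution=0.2))
        path = tmp_path / "mesh.off"
        syn.save_mesh_off(mesh, path)
        back = syn.load_mesh_off(path)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-8)
        np.testing.assert_array_equal(back.faces, mesh.faces)

    def test_gus_image_sidecar(self, tmp_path):
        cmap = syn.gen_cell_map(0.2, 0.1, 300.0, seed=1)
        image, _ = syn.render_gus_image(cmap)
        path = tmp_path / "img.png"
        syn.save_gus_image(image, path)
        assert path.exists() and path.with_suffix(".png.json").exists()
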