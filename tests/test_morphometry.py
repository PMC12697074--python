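"""Segmentation chain and nanoscale distance measurements."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import voromorph as vm
from voromorph.morphometry import ImageError
from voromorph.synthetic import CapsuleParams, RenderParams


def make_image(arr, nm_per_px=2.0):
    return vm.GrayImage(np.asarray(arr, dtype=float), nm_per_px)


# ---------------------------------------------------------------------------
# preprocess

class TestPreprocess:
    def test_constant_image_has_no_edges(self):
        img = make_image(np.full((16, 16), 0.4))
        out = vm.preprocess(img, edge_emphasis=True, smoothing_scale=0.0)
        assert np.all(out.pixels == 0.0)

    def test_step_edge_response_peaks_at_the_step(self):
        arr = np.zeros((20, 20))
        arr[:, 10:] = 1.0
        out = vm.preprocess(make_image(arr), edge_emphasis=True, smoothing_scale=0.0)
        col_response = out.pixels[5:-5].mean(axis=0)
        assert col_response.argmax() in (9, 10)
        assert col_response[0] == 0.0

    def test_matches_handcoded_gradient_and_gaussian_reference(self):
        """Independent reference: explicit 3x3 Sobel kernels and an explicit
        truncated-Gaussian separable convolution."""
        rng = np.random.default_rng(42)
        arr = rng.uniform(0, 1, (32, 32))
        out = vm.preprocess(make_image(arr), edge_emphasis=True, smoothing_scale=1.5)

        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
        gx = ndi.convolve(arr, kx, mode="reflect")
        gy = ndi.convolve(arr, kx.T, mode="reflect")
        g = np.hypot(gx, gy)
        g = g / g.max()
        sigma = 1.5
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        ref = ndi.convolve1d(g, kernel, axis=0, mode="reflect")
        ref = ndi.convolve1d(ref, kernel, axis=1, mode="reflect")
        np.testing.assert_allclose(out.pixels, np.clip(ref, 0, 1), atol=1e-6)

    def test_negative_smoothing_rejected(self):
        with pytest.raises(ImageError):
            vm.preprocess(make_image(np.zeros((4, 4))), smoothing_scale=-1.0)


# ---------------------------------------------------------------------------
# binarize / area fraction

class TestBinarize:
    def test_two_valued_image_splits_at_threshold_between(self):
        arr = np.full((10, 10), 0.2)
        arr[:, 5:] = 0.8
        mask = vm.binarize(make_image(arr), method="otsu")
        assert np.array_equal(mask.pixels, arr > 0.5)

    def test_fixed_level_on_checkerboard(self):
        arr = np.indices((8, 8)).sum(axis=0) % 2
        mask = vm.binarize(make_image(arr.astype(float)), method="fixed", level=0.5)
        assert np.array_equal(mask.pixels, arr == 1)

    def test_dark_polarity_inverts_selection(self):
        arr = np.full((10, 10), 0.2)
        arr[:, 5:] = 0.8
        mask = vm.binarize(make_image(arr), method="otsu", foreground="dark")
        assert np.array_equal(mask.pixels, arr < 0.5)

    def test_constant_image_has_no_otsu_threshold(self):
        with pytest.raises(ImageError, match="constant"):
            vm.binarize(make_image(np.full((8, 8), 0.3)), method="otsu")

    def test_fixed_method_requires_level(self):
        with pytest.raises(ImageError):
            vm.binarize(make_image(np.zeros((4, 4))), method="fixed")


class TestAreaFraction:
    def test_all_foreground(self):
        mask = vm.BinaryMask(np.ones((5, 5), dtype=bool), 1.0)
        assert vm.area_fraction(mask) == (100.0, 0.0)

    def test_checkerboard_is_half(self):
        arr = (np.indices((8, 8)).sum(axis=0) % 2).astype(bool)
        fg, bg = vm.area_fraction(vm.BinaryMask(arr, 1.0))
        assert fg == 50.0 and bg == 50.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sums_to_100_and_complement_swaps(self, seed):
        rng = np.random.default_rng(seed)
        mask = vm.BinaryMask(rng.random((31, 17)) > rng.random(), 1.0)
        fg, bg = vm.area_fraction(mask)
        assert fg + bg == 100.0
        fg2, bg2 = vm.area_fraction(mask.complement())
        assert fg2 == pytest.approx(bg, abs=1e-12)
        assert bg2 == pytest.approx(fg, abs=1e-12)


# ---------------------------------------------------------------------------
# pore sites

class TestInferPoreSites:
    def test_three_disc_centroids(self):
        walls = np.ones((60, 60), dtype=bool)
        centers = [(15, 15), (15, 45), (45, 30)]
        yy, xx = np.mgrid[0:60, 0:60]
        for r, c in centers:
            walls[np.hypot(yy - r, xx - c) < 8] = False
        sites = vm.infer_pore_sites(vm.BinaryMask(walls, 2.0))
        assert len(sites) == 3
        recovered = {(round(-p[1]), round(p[0])) for p in sites.points}
        for r, c in centers:
            assert any(abs(rr - r) <= 0.5 and abs(cc - c) <= 0.5 for rr, cc in recovered)

    @staticmethod
    def _interior(points_px, size_px, margin_px):
        return (
            (points_px[:, 0] > margin_px) & (points_px[:, 0] < size_px - margin_px)
            & (points_px[:, 1] < -margin_px) & (points_px[:, 1] > -(size_px - margin_px))
        )

    def test_roundtrip_from_rendered_voronoi_walls(self, default_params):
        """Noise-free render of a regular lattice: every interior pore
        centroid returns the generating site within 2 px (border pores are
        clipped by the frame, shifting their centroids)."""
        true_sites = vm.sample_pore_centers(
            default_params, (800.0, 800.0), rng_seed=5, jitter_sd=0.0
        )
        sample = vm.render_capsule_cross_section(
            true_sites, default_params,
            RenderParams(noise_sd=0.0, blur_sigma=0.0, rng_seed=0),
            orientation="horizontal",
        )
        inferred = vm.infer_pore_sites(sample.truth_mask)
        nmpp = sample.truth_mask.nm_per_px
        true_px = true_sites.points / nmpp
        interior = self._interior(true_px, 400, default_params.lattice_constant / nmpp)
        assert interior.sum() >= 10
        for p in true_px[interior]:
            assert np.min(np.hypot(*(inferred.points - p).T)) <= 2.0

    def test_noisy_render_recovers_most_interior_sites(self, horizontal_sample):
        """Default jitter + noise: >= 90% of interior sites recovered within
        5 px through the full segmentation chain."""
        img = horizontal_sample.image
        mask = vm.binarize(
            vm.preprocess(img, edge_emphasis=False, smoothing_scale=1.0)
        )
        inferred = vm.infer_pore_sites(mask)
        nmpp = mask.nm_per_px
        true_px = horizontal_sample.true_sites.points / nmpp
        size_px = img.shape[0]
        interior = self._interior(true_px, size_px, 115.0 / nmpp)
        hits = sum(
            np.min(np.hypot(*(inferred.points - p).T)) <= 5.0
            for p in true_px[interior]
        )
        assert hits / interior.sum() >= 0.9

    def test_too_few_components_rejected(self):
        walls = np.ones((20, 20), dtype=bool)
        walls[5:10, 5:10] = False
        with pytest.raises(ImageError, match=">= 3"):
            vm.infer_pore_sites(vm.BinaryMask(walls, 1.0))


# ---------------------------------------------------------------------------
# pore geometry

class TestMeasurePoreGeometry:
    def test_single_circular_pore_diameter(self):
        walls = np.ones((120, 120), dtype=bool)
        yy, xx = np.mgrid[0:120, 0:120]
        walls[np.hypot(yy - 60, xx - 60) <= 20.0] = False  # 40 px pore
        rep = vm.measure_pore_geometry(
            vm.BinaryMask(walls, 2.5), mode="horizontal"
        )
        s = rep.summary("pore_diameter")
        assert s.n == 1
        assert s.mean == pytest.approx(100.0, abs=2.5)  # one-pixel tolerance

    def test_border_clipped_pores_are_excluded(self):
        walls = np.ones((60, 60), dtype=bool)
        yy, xx = np.mgrid[0:60, 0:60]
        walls[np.hypot(yy - 30, xx - 30) <= 10] = False  # interior pore
        walls[np.hypot(yy - 0, xx - 30) <= 10] = False  # clipped at border
        rep = vm.measure_pore_geometry(vm.BinaryMask(walls, 1.0), mode="horizontal")
        assert rep.summary("pore_diameter").n == 1

    def test_vertical_comb_depths(self):
        mask = np.zeros((100, 200), dtype=bool)
        mask[70:90, :] = True  # dense layer + wall band
        for i, depth in enumerate([30, 40, 50, 40]):
            c = 25 + i * 50
            mask[70 - depth: 70, c - 3: c + 4] = True
        rep = vm.measure_pore_geometry(vm.BinaryMask(mask, 2.0), mode="vertical")
        vals = sorted(rep.values("pore_depth"))
        assert vals == [60.0, 80.0, 80.0, 100.0]

    def test_rotation_invariance_of_diameters(self, horizontal_sample):
        mask = horizontal_sample.truth_mask
        rep = vm.measure_pore_geometry(mask, mode="horizontal")
        rot = vm.BinaryMask(np.rot90(mask.pixels), mask.nm_per_px)
        rep_rot = vm.measure_pore_geometry(rot, mode="horizontal")
        assert sorted(rep.values("pore_diameter")) == pytest.approx(
            sorted(rep_rot.values("pore_diameter"))
        )

    def test_no_pores_rejected(self):
        with pytest.raises(ImageError):
            vm.measure_pore_geometry(
                vm.BinaryMask(np.ones((20, 20), dtype=bool), 1.0), mode="horizontal"
            )

    def test_calibration_equivariance(self, horizontal_sample):
        mask = horizontal_sample.truth_mask
        a = vm.measure_pore_geometry(mask, mode="horizontal").values("pore_diameter")
        scaled = vm.BinaryMask(mask.pixels, mask.nm_per_px * 3.0)
        b = vm.measure_pore_geometry(scaled, mode="horizontal").values("pore_diameter")
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-12)


# ---------------------------------------------------------------------------
# layer thickness

def annulus_mask(r_in=100.0, r_out=120.0, pad=10):
    half = int(r_out) + pad
    size = 2 * half + 1
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rr = np.hypot(yy - half, xx - half)
    return (rr >= r_in) & (rr < r_out)


class TestMeasureLayerThickness:
    def test_perfect_annulus_thickness_on_every_ray(self):
        rep = vm.measure_layer_thickness(
            vm.BinaryMask(annulus_mask(), 2.0), kind="capsule_thickness", n_rays=36
        )
        vals = rep.values("capsule_thickness")
        assert len(vals) == 36
        np.testing.assert_allclose(vals, 40.0, atol=2.0)

    def test_broken_annulus_skips_gap_rays(self):
        mask = annulus_mask()
        h, w = mask.shape
        # cut a narrow radial slit to the right of the centre
        mask[h // 2 - 4: h // 2 + 5, w // 2:] = False
        rep = vm.measure_layer_thickness(
            vm.BinaryMask(mask, 2.0), kind="cell_wall_thickness", n_rays=36
        )
        n = rep.summary("cell_wall_thickness").n
        assert 0 < n < 36

    def test_non_annular_mask_rejected(self):
        solid = np.zeros((50, 50), dtype=bool)
        solid[10:40, 10:40] = True  # filled square: no interior hole
        with pytest.raises(ImageError, match="annular"):
            vm.measure_layer_thickness(vm.BinaryMask(solid, 1.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ImageError):
            vm.measure_layer_thickness(
                vm.BinaryMask(annulus_mask(), 1.0), kind="banana"
            )


# ---------------------------------------------------------------------------
# cell major axis

class TestCellMajorAxis:
    def test_rectangle_major_axis_in_um(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:40, 20:70] = True  # 30 x 50 px
        rep = vm.cell_major_axis(vm.BinaryMask(mask, 20.0))
        s = rep.summary("cell_major_axis")
        assert s.n == 1
        assert s.mean == pytest.approx(1.0)  # 50 px * 20 nm = 1.0 um

    def test_touching_cells_measured_as_one_cluster(self):
        mask = np.zeros((60, 120), dtype=bool)
        yy, xx = np.mgrid[0:60, 0:120]
        mask[np.hypot(yy - 30, xx - 40) <= 15] = True
        mask[np.hypot(yy - 30, xx - 68) <= 15] = True  # overlapping discs
        rep = vm.cell_major_axis(vm.BinaryMask(mask, 20.0))
        s = rep.summary("cell_major_axis")
        assert s.n == 1
        # the cluster spans both discs: (68 + 15) - (40 - 15) = 58 px
        assert s.mean == pytest.approx(58 * 20.0 / 1000.0, abs=0.08)
        assert s.mean > 2 * 15 * 20.0 / 1000.0  # longer than one cell alone

    def test_empty_mask_rejected(self):
        with pytest.raises(ImageError, match="empty"):
            vm.cell_major_axis(vm.BinaryMask(np.zeros((10, 10), dtype=bool), 1.0))


# ---------------------------------------------------------------------------
# full-pipeline area recovery (property)

class TestFullPipelineAreaRecovery:
    def test_recovers_fractions_across_the_density_range(self):
        """Over synthetic biofilm sections with true cell fractions spanning
        30-70%, the blur+Otsu pipeline stays within 3 percentage points of
        truth in at least 18 of 20 sections."""
        rng = np.random.default_rng(77)
        hits = 0
        for k in range(20):
            target = float(rng.uniform(30.0, 70.0))
            sample = vm.render_biofilm_section(
                target, cell_size_px=40.0, extent=(256, 256),
                render=RenderParams(nm_per_px=10.0, noise_sd=0.05,
                                    blur_sigma=1.2, rng_seed=1000 + k),
            )
            mask = vm.binarize(
                vm.preprocess(sample.image, edge_emphasis=False, smoothing_scale=1.5)
            )
            fg, _ = vm.area_fraction(mask)
            if abs(fg - sample.truth["cell_fraction_pct"]) < 3.0:
                hits += 1
        assert hits >= 18
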