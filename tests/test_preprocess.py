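import numpy as np
import pytest

from mtfe import (
    VoxelImage,
    align_to_axis,
    connectivity_filter,
    fit_plane,
    gaussian_filter,
    histogram_threshold,
    segment,
)
from mtfe.preprocess import FittedPlane, gaussian_kernel_3x3x3


class TestFitPlane:
    def test_horizontal_plane_exact(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.random(20), rng.random(20), np.full(20, 5.0)])
        p = fit_plane(pts)
        np.testing.assert_allclose(p.normal, [0, 0, 1], atol=1e-12)
        assert p.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_45_degree_plane(self):
        pts = [(x, y, x) for x in range(5) for y in range(5)]
        p = fit_plane(pts)
        np.testing.assert_allclose(
            p.normal, np.array([-1.0, 0.0, 1.0]) / np.sqrt(2), atol=1e-10
        )
        assert p.rms_residual == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_noise_rms(self):
        # alternate +/- eps on a large flat grid: TLS keeps the horizontal
        # plane and the orthogonal RMS equals eps (closed form)
        eps = 1e-3
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        z = np.where((xs + ys) % 2 == 0, eps, -eps)
        p = fit_plane(np.column_stack([xs.ravel(), ys.ravel(), z.ravel()]))
        assert abs(p.normal[2]) > 0.999999
        assert p.rms_residual == pytest.approx(eps, rel=1e-6)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_plane([(t, t, t) for t in range(5)])

    def test_normal_is_unit_with_nonneg_z(self):
        rng = np.random.default_rng(2)
        pts = rng.random((30, 3))
        p = fit_plane(pts)
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-10)
        assert p.normal[2] >= 0


class TestAlignToAxis:
    def test_horizontal_plane_is_identity(self):
        rng = np.random.default_rng(1)
        img = VoxelImage(rng.random((8, 8, 8)), 0.0104)
        plane = FittedPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3), 0.0)
        out = align_to_axis(img, plane)
        np.testing.assert_allclose(out.data, img.data, atol=1e-9)

    def test_constant_image_invariant(self):
        img = VoxelImage(np.full((10, 10, 10), 42.0), 0.0104)
        plane = FittedPlane(
            np.array([0.3, 0.1, 0.9]) / np.linalg.norm([0.3, 0.1, 0.9]),
            np.zeros(3), 0.0,
        )
        out = align_to_axis(img, plane)
        np.testing.assert_allclose(out.data, 42.0, rtol=1e-7)

    def test_tilted_slab_becomes_axis_aligned(self):
        # slab normal tilted ~11 deg about y; after alignment the lower
        # surface should sit on one index plane to within one voxel
        n = np.array([np.sin(0.2), 0.0, np.cos(0.2)])
        shape = (40, 40, 40)
        idx = np.indices(shape).reshape(3, -1).T + 0.5
        center = np.array(shape) / 2.0
        d = (idx - center) @ n
        data = np.where((d > -4) & (d < 4), 200.0, 10.0).reshape(shape)
        img = VoxelImage(data, 1.0)
        plane = FittedPlane(n, center, 0.0)
        out = align_to_axis(img, plane)
        core = out.data[15:25, 15:25, :]  # central columns, away from edges
        zlo = np.argmax(core > 100.0, axis=2)
        assert zlo.max() - zlo.min() <= 1


class TestGaussianFilter:
    def test_constant_unchanged(self):
        img = VoxelImage(np.full((6, 6, 6), 7.0), 1.0)
        np.testing.assert_allclose(gaussian_filter(img).data, 7.0, rtol=1e-12)

    def test_impulse_response_is_kernel(self):
        z = np.zeros((9, 9, 9))
        z[4, 4, 4] = 1.0
        out = gaussian_filter(VoxelImage(z, 1.0)).data
        k = gaussian_kernel_3x3x3()
        np.testing.assert_allclose(out[3:6, 3:6, 3:6], k, atol=1e-15)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_preserved_under_reflect(self):
        rng = np.random.default_rng(0)
        img = VoxelImage(rng.random((8, 8, 8)), 1.0)
        out = gaussian_filter(img)
        assert out.data.mean() == pytest.approx(img.data.mean(), rel=1e-10)

    def test_translation_equivariance_away_from_borders(self):
        rng = np.random.default_rng(4)
        base = np.zeros((12, 12, 12))
        base[3:7, 3:7, 3:7] = rng.random((4, 4, 4))
        shifted = np.roll(base, 2, axis=0)
        f1 = gaussian_filter(VoxelImage(base, 1.0)).data
        f2 = gaussian_filter(VoxelImage(shifted, 1.0)).data
        np.testing.assert_allclose(np.roll(f1, 2, axis=0)[4:10], f2[4:10], atol=1e-12)


class TestHistogramThreshold:
    def test_two_gaussian_mixture(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(100, 10, 20000), rng.normal(300, 10, 8000)])
        t = histogram_threshold(VoxelImage(v.reshape(20, 20, 70), 1.0))
        bin_w = (v.max() - v.min()) / 256
        assert t.background_peak == pytest.approx(100, abs=3 * bin_w)
        assert t.bone_peak == pytest.approx(300, abs=3 * bin_w)
        assert t.threshold == pytest.approx(200, abs=3 * bin_w)

    def test_two_delta_populations(self):
        data = np.concatenate([np.full(4000, 50.0), np.full(1000, 250.0)])
        t = histogram_threshold(VoxelImage(data.reshape(10, 10, 50), 1.0))
        assert t.threshold == pytest.approx(150.0, abs=1.0)

    def test_threshold_is_exact_peak_midpoint(self):
        rng = np.random.default_rng(9)
        v = np.concatenate([rng.normal(80, 5, 5000), rng.normal(240, 12, 5000)])
        t = histogram_threshold(VoxelImage(v.reshape(10, 10, 100), 1.0))
        assert t.threshold == (t.background_peak + t.bone_peak) / 2
        assert t.background_peak < t.threshold < t.bone_peak

    def test_unimodal_rejected_with_advice(self):
        rng = np.random.default_rng(11)
        v = rng.normal(100, 5, 8000)
        with pytest.raises(ValueError, match="manual threshold"):
            histogram_threshold(VoxelImage(v.reshape(20, 20, 20), 1.0))

    def test_phantom_threshold_between_modes(self):
        from mtfe import PhantomSpec, make_phantom

        spec = PhantomSpec(noise_sd=4.0, seed=3)
        grey, mask, _ = make_phantom(spec)
        t = histogram_threshold(grey)
        assert spec.background_grey < t.threshold < spec.bone_grey_mode


class TestSegment:
    def test_extremes(self):
        img = VoxelImage(np.arange(8.0).reshape(2, 2, 2), 1.0)
        assert segment(img, -1.0).data.all()
        assert not segment(img, 100.0).data.any()

    def test_threshold_value_included(self):
        img = VoxelImage(np.full((1, 1, 1), 5.0), 1.0)
        assert segment(img, 5.0).data[0, 0, 0] == 1


class TestConnectivityFilter:
    def test_keeps_largest_component(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[0:4, 0:5, 0:5] = 1  # 100 voxels
        m[7:8, 7:8, 3:8] = 1  # 5 voxels
        out = connectivity_filter(VoxelImage(m, 1.0, value_kind="mask"))
        assert out.data.sum() == 100
        assert out.data[7, 7, 5] == 0

    def test_edge_touching_voxels_are_separate(self):
        m = np.zeros((3, 3, 3), np.uint8)
        m[0, 0, 0] = 1
        m[1, 1, 0] = 1  # shares only an edge — 6-connectivity splits them
        out = connectivity_filter(VoxelImage(m, 1.0, value_kind="mask"))
        # tie broken toward the lower linear index
        assert out.data.sum() == 1
        assert out.data[0, 0, 0] == 1

    def test_tube_with_specks(self, small_tube):
        _, (_, mask, _) = small_tube
        n_tube = int(mask.data.sum())
        dirty = mask.data.copy()
        dirty[0, 0, 0] = dirty[0, 1, 5] = dirty[1, 0, 9] = 1
        out = connectivity_filter(VoxelImage(dirty, mask.spacing, value_kind="mask"))
        assert out.data.sum() == n_tube
        np.testing.assert_array_equal(out.data, mask.data)

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(13)
        m = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8)
        img = VoxelImage(m, 1.0, value_kind="mask")
        once = connectivity_filter(img)
        twice = connectivity_filter(once)
        np.testing.assert_array_equal(once.data, twice.data)
        assert once.data.sum() <= m.sum()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            connectivity_filter(
                VoxelImage(np.zeros((2, 2, 2), np.uint8), 1.0, value_kind="mask")
            )
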