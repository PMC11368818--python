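"""Forward imaging: convolution oracle, projection, flux, binning, noise."""

import numpy as np
import pytest

from microvista.geometry import Spherocylinder
from microvista.imaging import (
    CameraModel,
    apply_camera_noise,
    convolve_layerwise,
    downsample_to_camera,
    render_scene,
    restrict_depth_of_field,
)
from microvista.layouts import isolated_layout
from microvista.psf import PSF3D, identity_psf


def brute_force_layerwise(volume, kernel):
    """Direct-summation oracle for the layerwise convolution (same-mode)."""
    nzv, ny, nx = volume.shape
    nzk, ky, kx = kernel.shape
    out = np.zeros((ny, nx))
    kc = (nzk - 1) // 2
    zc = (nzv - 1) / 2.0
    for iz in range(nzv):
        kz = kc + int(round(iz - zc))
        kern = kernel[kz]
        for y in range(ny):
            for x in range(nx):
                acc = 0.0
                for dy in range(ky):
                    for dx in range(kx):
                        yy = y - (dy - ky // 2)
                        xx = x - (dx - kx // 2)
                        if 0 <= yy < ny and 0 <= xx < nx:
                            acc += volume[iz, yy, xx] * kern[dy, dx]
                out[y, x] += acc
    return out * nzk


def make_gaussian_psf(nz=5, n=21, voxel=0.1, sigma=0.15):
    """Synthetic kernel with exactly equal per-slice energy."""
    y, x = np.mgrid[:n, :n]
    r2 = ((y - n // 2) ** 2 + (x - n // 2) ** 2) * voxel**2
    sl = np.exp(-r2 / (2 * sigma**2))
    data = np.repeat(sl[None], nz, axis=0)
    return PSF3D(data, voxel, voxel, nz // 2, "theoretical", None).normalize()


class TestConvolveLayerwise:
    def test_matches_brute_force_oracle(self, rng):
        vol = rng.random((5, 7, 7))
        kern = rng.random((5, 5, 5))
        psf = PSF3D(kern, 0.1, 0.1, 2, "theoretical", None).normalize()
        fast = convolve_layerwise(vol, psf, 0.1, 0.1, method="direct")
        fast_fft = convolve_layerwise(vol, psf, 0.1, 0.1, method="fft")
        oracle = brute_force_layerwise(vol, psf.data)
        assert np.max(np.abs(fast - oracle)) < 1e-10
        assert np.max(np.abs(fast_fft - oracle)) < 1e-10

    def test_identity_psf_is_projection(self, rng):
        vol = rng.random((7, 16, 16))
        out = convolve_layerwise(vol, identity_psf(), 0.05, 0.05)
        assert np.allclose(out, vol.sum(axis=0))

    def test_single_emitter_reproduces_focal_slice(self):
        psf = make_gaussian_psf()
        vol = np.zeros((1, 21, 21))
        vol[0, 10, 10] = 1.0
        out = convolve_layerwise(vol, psf, 0.1, 0.1)
        assert np.allclose(out, psf.data[2] * 5)

    def test_linearity_and_translation(self, rng):
        psf = make_gaussian_psf()
        a = np.zeros((3, 31, 31))
        b = np.zeros((3, 31, 31))
        a[1, 10, 10] = 2.0
        b[1, 20, 18] = 1.0
        out_sum = convolve_layerwise(a + b, psf, 0.1, 0.1)
        out_a = convolve_layerwise(a, psf, 0.1, 0.1)
        out_b = convolve_layerwise(b, psf, 0.1, 0.1)
        assert np.allclose(out_sum, out_a + out_b, atol=1e-12)
        # translation equivariance
        shifted = np.roll(a, (5, 3), axis=(1, 2))
        out_shifted = convolve_layerwise(shifted, psf, 0.1, 0.1)
        assert np.allclose(out_shifted, np.roll(out_a, (5, 3), axis=(0, 1)),
                           atol=1e-12)

    def test_flux_conservation_contained_kernel(self):
        psf = make_gaussian_psf()
        vol = np.zeros((5, 61, 61))
        vol[2, 30, 30] = 3.0
        vol[1, 28, 33] = 2.0
        out = convolve_layerwise(vol, psf, 0.1, 0.1)
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_voxel_mismatch_rejected(self, rng):
        psf = make_gaussian_psf(voxel=0.1)
        with pytest.raises(ValueError):
            convolve_layerwise(rng.random((3, 5, 5)), psf, 0.2, 0.1)


class TestDepthOfField:
    def test_single_plane_keeps_only_focus(self):
        psf = make_gaussian_psf(nz=5)
        cut = restrict_depth_of_field(psf, psf.voxel_z_um)
        assert cut.data[2].sum() > 0
        assert cut.data[0].sum() == 0 and cut.data[4].sum() == 0

    def test_full_extent_unchanged(self):
        psf = make_gaussian_psf(nz=5)
        cut = restrict_depth_of_field(psf, 5 * psf.voxel_z_um)
        assert np.array_equal(cut.data, psf.data)

    def test_truncation_strictly_removes_flux(self):
        psf = make_gaussian_psf(nz=5)
        cut = restrict_depth_of_field(psf, psf.voxel_z_um)
        assert cut.data.sum() < psf.data.sum()

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            restrict_depth_of_field(make_gaussian_psf(), 0.0)


class TestDownsample:
    def test_identity_factor(self, rng):
        img = rng.random((8, 8))
        assert np.array_equal(downsample_to_camera(img, 1), img)

    def test_block_sum(self):
        out = downsample_to_camera(np.ones((4, 4)), 2)
        assert np.array_equal(out, np.full((2, 2), 4.0))

    def test_flux_preserved_exactly(self, rng):
        img = rng.random((12, 18))
        assert downsample_to_camera(img, 3).sum() == pytest.approx(
            img.sum(), rel=1e-14
        )

    def test_pad_and_warn_on_indivisible(self, rng):
        with pytest.warns(UserWarning):
            out = downsample_to_camera(rng.random((5, 5)), 2)
        assert out.shape == (3, 3)


class TestCameraNoise:
    def test_dark_frame_moments(self):
        cam = CameraModel()
        img = apply_camera_noise(np.zeros((400, 400)), cam, rng=0).astype(float)
        assert img.mean() == pytest.approx(100.0, abs=0.1)
        assert img.var() == pytest.approx(2.9**2 * 8, rel=0.05)

    def test_photon_transfer_slope(self):
        cam = CameraModel()
        means, varis = [], []
        for n in (50, 200, 800):
            img = apply_camera_noise(np.full((300, 300), float(n)), cam, rng=n)
            img = img.astype(float) - cam.baseline_adu
            means.append(img.mean())
            varis.append(img.var())
        # shot-noise-limited: variance ≈ gain * mean + const
        slope = (varis[-1] - varis[0]) / (means[-1] - means[0])
        assert slope == pytest.approx(cam.sensitivity_adu_per_electron, rel=0.05)

    def test_seeded_reproducibility(self):
        cam = CameraModel()
        a = apply_camera_noise(np.full((32, 32), 10.0), cam, rng=7)
        b = apply_camera_noise(np.full((32, 32), 10.0), cam, rng=7)
        assert np.array_equal(a, b)


class TestRenderScene:
    def test_identity_psf_image_support_equals_mask(self):
        lay = isolated_layout(Spherocylinder(4.0, 0.5), density=2000.0,
                              margin_um=1.0)
        pair = render_scene(lay, identity_psf(), rng=0, voxel_xy_um=0.065,
                            voxel_z_um=0.25)
        img_support = pair.image > 0
        mask = pair.masks > 0
        # all light inside the mask, and the mask is well covered
        assert (img_support & ~mask).sum() / img_support.sum() < 0.15
        assert (img_support & mask).sum() / mask.sum() > 0.8

    def test_diffraction_spreads_beyond_mask(self, small_tpsf):
        lay = isolated_layout(Spherocylinder(4.0, 0.5), density=2000.0,
                              margin_um=2.0, pixel_size_um=0.08)
        pair = render_scene(lay, small_tpsf, rng=0, voxel_xy_um=0.04,
                            voxel_z_um=0.1)
        outside = pair.image[pair.masks == 0].sum()
        assert outside > 0.05 * pair.image.sum()

    def test_superposition_of_disjoint_scenes(self, rng):
        from microvista.layouts import SceneLayout

        psf = make_gaussian_psf(nz=15, voxel=0.065)
        c1 = Spherocylinder(3.0, 0.4, center_xyz_um=(3.0, 2.5, 0.0), cell_id=1)
        c2 = Spherocylinder(3.0, 0.4, center_xyz_um=(3.0, 7.5, 0.0),
                            orientation_rad=1.0, cell_id=2)
        mk = lambda cells, dens: SceneLayout(
            cells, dens, (154, 100), 0.065, "scatter"
        )
        kw = dict(voxel_xy_um=0.065, voxel_z_um=0.065)
        both = render_scene(mk([c1, c2], [300.0, 300.0]), psf, rng=5, **kw)
        only1 = render_scene(mk([c1, c2], [300.0, 0.0]), psf, rng=5, **kw)
        only2 = render_scene(mk([c1, c2], [0.0, 300.0]), psf, rng=5, **kw)
        assert np.allclose(both.image, only1.image + only2.image, atol=1e-9)

    def test_reproducible_from_seed(self):
        lay = isolated_layout(Spherocylinder(4.0, 0.5), density=500.0)
        psf = make_gaussian_psf(nz=17, voxel=0.065)
        kw = dict(voxel_xy_um=0.065, voxel_z_um=0.065, noise=True)
        a = render_scene(lay, psf, rng=3, **kw)
        b = render_scene(lay, psf, rng=3, **kw)
        assert np.array_equal(a.image, b.image)
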