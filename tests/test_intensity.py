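"""Intensity quantification: background, per-cell means, bleedthrough,
position metrics, CV distortion, Richardson-Lucy."""

import numpy as np
import pytest

from microvista.geometry import Spherocylinder
from microvista.imaging import render_scene
from microvista.intensity import (
    array_bleedthrough_heatmap,
    background_subtract,
    colony_intensity_trend,
    colony_position_metrics,
    cv_crossover,
    isolated_cell_retention,
    observed_cv,
    per_cell_mean_intensity,
    richardson_lucy_deconvolve,
)
from microvista.layouts import SceneLayout, grow_monolayer_colony, isolated_layout
from microvista.psf import effective_psf_longrange


class TestBackgroundSubtract:
    def test_constant_image_to_zero(self):
        assert np.allclose(background_subtract(np.full((20, 20), 7.0)), 0.0)

    def test_offset_removed_exactly(self, rng):
        img = np.zeros((100, 100))
        img[40:60, 40:60] = rng.uniform(50, 80, (20, 20))  # 4% signal pixels
        offset = 13.25
        out = background_subtract(img + offset)
        assert np.allclose(out[:20, :20], 0.0)
        assert np.allclose(out[40:60, 40:60], img[40:60, 40:60], atol=1e-9)

    def test_idempotent_on_zero_background(self):
        img = np.zeros((50, 50))
        img[20:25, 20:25] = 40.0
        once = background_subtract(img)
        assert np.allclose(background_subtract(once), once)


class TestPerCellMean:
    def test_uniform_image(self):
        masks = np.zeros((10, 10), dtype=int)
        masks[2:4, 2:4] = 1
        masks[6:9, 6:9] = 2
        recs = per_cell_mean_intensity(np.full((10, 10), 5.0), masks)
        assert [r.mean_intensity for r in recs] == [5.0, 5.0]
        assert [r.mask_area_px for r in recs] == [4, 9]

    def test_symmetric_cells_equal_means(self):
        masks = np.zeros((10, 20), dtype=int)
        masks[4:6, 2:5] = 1
        masks[4:6, 15:18] = 2
        img = np.zeros((10, 20))
        img[masks == 1] = 3.0
        img[masks == 2] = 3.0
        recs = per_cell_mean_intensity(img, masks)
        assert recs[0].mean_intensity == recs[1].mean_intensity

    def test_missing_label_warns(self):
        import pandas as pd

        masks = np.zeros((5, 5), dtype=int)
        masks[1:3, 1:3] = 1
        truth = pd.DataFrame({"cell_id": [1, 2], "true_mean": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            recs = per_cell_mean_intensity(np.ones((5, 5)), masks, truth)
        assert len(recs) == 1


class TestObservedCV:
    def test_identical_intensities_zero(self):
        assert observed_cv(np.array([4.0, 4.0, 4.0])) == 0.0

    def test_known_sample(self):
        vals = np.array([1.0, 2.0, 3.0])
        assert observed_cv(vals) == pytest.approx(1.0 / 2.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            observed_cv(np.array([1.0]))
        with pytest.raises(ValueError):
            observed_cv(np.array([0.0, 0.0]))


class TestPositionMetrics:
    def test_single_centered_cell(self):
        masks = np.zeros((30, 30), dtype=int)
        masks[12:18, 12:18] = 1
        df = colony_position_metrics(masks)
        assert df["d_c_over_D"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert df["neighbour_degree"].iloc[0] == 0

    def test_two_touching_cells_degree_one(self):
        masks = np.zeros((20, 40), dtype=int)
        masks[5:15, 5:20] = 1
        masks[5:15, 20:35] = 2
        df = colony_position_metrics(masks)
        assert list(df["neighbour_degree"]) == [1, 1]

    def test_square_lattice_interior_degree_four(self):
        # 5x5 lattice of 8x8 blocks separated by 2-px gaps (< 2*4 dilation)
        masks = np.zeros((60, 60), dtype=int)
        lab = 0
        for i in range(5):
            for j in range(5):
                lab += 1
                masks[2 + 10 * i : 10 + 10 * i, 2 + 10 * j : 10 + 10 * j] = lab
        df = colony_position_metrics(masks).set_index("cell_id")
        assert df.loc[13, "neighbour_degree"] == 4  # interior cell
        assert df.loc[1, "neighbour_degree"] == 2  # corner cell
        # centre cell sits at the colony centroid
        assert df.loc[13, "d_c_over_D"] < df.loc[1, "d_c_over_D"]


class TestRichardsonLucy:
    def test_delta_kernel_is_identity(self, rng):
        img = rng.uniform(1, 5, (32, 32))
        kern = np.zeros((5, 5))
        kern[2, 2] = 1.0
        out = richardson_lucy_deconvolve(img, kern, iterations=17)
        assert np.allclose(out, img, rtol=1e-10)

    def test_sharpens_blurred_point_and_conserves_flux(self):
        from scipy.signal import fftconvolve

        kern = np.outer(*2 * [np.exp(-((np.arange(15) - 7) ** 2) / 18.0)])
        kern /= kern.sum()
        src = np.zeros((64, 64))
        src[32, 32] = 100.0
        blurred = fftconvolve(src, kern, mode="same")
        peaks = []
        for it in (5, 30, 100):
            out = richardson_lucy_deconvolve(blurred, kern, iterations=it)
            peaks.append(out.max())
            assert out.min() >= -1e-12 * out.max()
            assert out.sum() == pytest.approx(blurred.sum(), rel=1e-3)
        assert peaks[0] < peaks[1] < peaks[2]

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError):
            richardson_lucy_deconvolve(np.ones((8, 8)), np.zeros((3, 3)))


@pytest.fixture(scope="module")
def epsf():
    return effective_psf_longrange()


@pytest.fixture(scope="module")
def small_colonies():
    snaps = grow_monolayer_colony(60, rng=11)
    return [s for s in snaps if s.n_cells in (1, 16, 32, 64)]


class TestColonyTrend:
    def test_trend_monotone_and_below_truth(self, epsf, small_colonies):
        df = colony_intensity_trend(small_colonies, epsf, rng=0,
                                    kernel_extent_um=12.0)
        ratios = df["mean_ratio"].to_numpy()
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] < 1.0
        # colony cells are brighter than the isolated cell
        assert ratios[-1] > 1.5 * ratios[0]

    def test_centre_cells_brighter(self, epsf, small_colonies):
        from scipy.stats import spearmanr

        snap = small_colonies[-1]
        pair = render_scene(snap, epsf, rng=1, voxel_xy_um=0.065,
                            voxel_z_um=0.25, kernel_extent_um=12.0)
        recs = per_cell_mean_intensity(pair.image, pair.masks, pair.truth)
        pos = colony_position_metrics(pair.masks).set_index("cell_id")
        inten = [r.mean_intensity for r in recs]
        dcd = [pos.loc[r.cell_id, "d_c_over_D"] for r in recs]
        rho, _ = spearmanr(dcd, inten)
        assert rho < -0.3


class TestBleedthrough:
    def test_monotone_in_pitch(self, epsf):
        tpl = Spherocylinder(5.0, 0.5)
        df = array_bleedthrough_heatmap(
            [1.0, 3.0, 8.0], [6.0], tpl, epsf, rings=1, rng=2,
            kernel_extent_um=12.0, n_seeds=1,
        )
        vals = df.sort_values("pitch_x_um")["bleedthrough_pct"].to_numpy()
        assert vals[0] > vals[1] > vals[2] >= 0


class TestCvCrossover:
    def test_crossover_interpolation(self):
        import pandas as pd

        curve = pd.DataFrame(
            {"true_cv": [0.0, 0.1, 0.2, 0.3],
             "observed_cv": [0.08, 0.12, 0.19, 0.25]}
        )
        # observed - true: +0.08, +0.02, -0.01, -0.05 -> crossing in (0.1, 0.2)
        x = cv_crossover(curve)
        assert 0.1 < x < 0.2

    def test_no_crossover_raises(self):
        import pandas as pd

        curve = pd.DataFrame(
            {"true_cv": [0.0, 0.1], "observed_cv": [0.05, 0.2]}
        )
        with pytest.raises(ValueError):
            cv_crossover(curve)


class TestIsolatedRetention:
    def test_isolated_cell_dimmer_than_truth(self, epsf):
        ratio = isolated_cell_retention(epsf, Spherocylinder(6.0, 0.5),
                                        rng=0, n_seeds=1,
                                        kernel_extent_um=12.0)
        assert 0.1 < ratio < 0.6
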