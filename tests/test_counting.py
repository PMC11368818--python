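"""Molecule counting: partition identity, merge statistics, corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microvista.counting import (
    CountPartition,
    MoleculeSample,
    defocus_correction_factor,
    macs_flatten,
    merge_probability,
    naive_partition,
    optimal_focus_shift,
    typical_cell,
    undercount_curve,
)
from microvista.geometry import axial_cross_section
from microvista.psf import DetectionProfile, OpticsConfig


class TestPartition:
    def test_single_centred_molecule_counted(self):
        s = MoleculeSample(np.array([[0.0, 0.0, 0.0]]), typical_cell())
        p = naive_partition(s)
        assert (p.n_counted, p.n_lost_defocus, p.n_lost_diffraction) == (1, 0, 0)

    def test_deep_molecule_lost_to_defocus(self):
        s = MoleculeSample(np.array([[0.0, 0.0, 0.3]]), typical_cell())
        p = naive_partition(s, dof_halfwidth_um=0.25)
        assert p.n_lost_defocus == 1
        assert p.n_counted == 0

    def test_close_pair_merges_to_one_spot(self):
        s = MoleculeSample(
            np.array([[0.0, 0.0, 0.0], [0.05, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            typical_cell(),
        )
        p = naive_partition(s)
        assert p.n_counted == 2
        assert p.n_lost_diffraction == 1

    @given(st.integers(1, 25), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_identity_holds(self, n, seed):
        s = MoleculeSample.draw(typical_cell(), n, rng=seed)
        p = naive_partition(s)
        assert p.n_lost_defocus + p.n_lost_diffraction + p.n_resolved == n
        assert 0 <= p.n_counted <= n

    def test_inconsistent_partition_rejected(self):
        with pytest.raises(ValueError):
            CountPartition(5, 1, 1, 1, 1)


class TestMergeProbability:
    def test_vanishing_rayleigh_radius(self):
        tiny = OpticsConfig(wavelength_um=0.01, na=1.49)
        p, _ = merge_probability(2, n_trials=300, rng=0, optics=tiny)
        assert p < 0.01

    def test_huge_rayleigh_radius_always_merges(self):
        huge = OpticsConfig(wavelength_um=20.0, na=1.2, n_immersion=1.518)
        p, _ = merge_probability(2, n_trials=300, rng=0, optics=huge)
        assert p == pytest.approx(1.0)

    def test_more_molecules_merge_more(self):
        p2, _ = merge_probability(2, n_trials=800, rng=1)
        p6, _ = merge_probability(6, n_trials=800, rng=1)
        assert p6 > p2

    def test_few_trials_warn(self):
        with pytest.warns(UserWarning):
            merge_probability(2, n_trials=50, rng=0)


class TestUndercountCurve:
    def test_undercount_grows_with_copy_number(self):
        df = undercount_curve([5, 15, 30], n_trials=300, rng=2)
        u = df["undercount_fraction"].to_numpy()
        assert u[0] < u[1] < u[2]

    def test_defocus_fraction_independent_of_n(self):
        df = undercount_curve([5, 15, 30], n_trials=600, rng=3)
        f = df["frac_lost_defocus"].to_numpy()
        assert np.max(np.abs(f - f.mean())) < 0.03

    def test_macs_cell_avoids_defocus_loss(self):
        flat, vol_ratio = macs_flatten()
        assert (flat.length_um, 2 * flat.radius_um, flat.depth_um) == (
            5.5, 2.0, 0.6
        )
        assert 1.0 < vol_ratio < 2.0  # trapped geometry is somewhat larger
        df = undercount_curve([15], cell=flat, n_trials=400, rng=4,
                              dof_halfwidth_um=0.3)
        assert df["frac_lost_defocus"].iloc[0] < 0.01
        df_round = undercount_curve([15], n_trials=400, rng=4)
        # flattening slashes the total undercount...
        assert (
            df["undercount_fraction"].iloc[0]
            < 0.5 * df_round["undercount_fraction"].iloc[0]
        )
        # ...and, with every molecule in focus in both geometries, the
        # expanded footprint also reduces diffraction merging
        df_round_focus = undercount_curve([15], n_trials=400, rng=4,
                                          dof_halfwidth_um=0.5)
        assert (
            df["frac_lost_diffraction"].iloc[0]
            < df_round_focus["frac_lost_diffraction"].iloc[0]
        )


def box_profile(z0, z1, n=401, lo=-2.0, hi=2.0):
    z = np.linspace(lo, hi, n)
    return z, ((z >= z0) & (z <= z1)).astype(float)


class TestFocusShiftAndCorrection:
    def test_symmetric_profiles_zero_shift(self):
        cell = typical_cell()
        z, a = axial_cross_section(cell)
        zd = np.linspace(-1, 1, 201)
        D = DetectionProfile(zd, np.exp(-(zd**2) / 0.08), 2.3, 500)
        assert optimal_focus_shift((z, a), D) == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self):
        cell = typical_cell()
        z, a = axial_cross_section(cell)
        zd = np.linspace(-1.5, 1.5, 301)
        base = np.exp(-((zd + 0.1) ** 2) / 0.05)  # asymmetric about 0
        d0 = DetectionProfile(zd, base, 2.3, 500)
        d_shift = DetectionProfile(zd + 0.3, base, 2.3, 500)
        s0 = optimal_focus_shift((z, a), d0)
        s1 = optimal_focus_shift((z, a), d_shift)
        # moving the detection peak up by +0.3 um moves the optimal focus
        # by exactly 0.3 um (opposite sign under the D(z - dz) convention)
        assert s1 - s0 == pytest.approx(-0.3, abs=1e-6)

    def test_matches_dense_scan_oracle(self, rng):
        cell = typical_cell()
        z, a = axial_cross_section(cell, n_points=801)
        zd = np.linspace(-1.2, 1.2, 241)
        vals = np.clip(np.exp(-(zd**2) / 0.1) + 0.3 * np.exp(
            -((zd - 0.4) ** 2) / 0.02), 0, 1)
        D = DetectionProfile(zd, vals, 2.3, 500)
        found = optimal_focus_shift((z, a), D, shift_step_um=0.002)
        shifts = np.arange(-1.0, 1.0, 0.0005)
        overlaps = [np.trapezoid(a * D.at(z - s), z) for s in shifts]
        assert found == pytest.approx(shifts[int(np.argmax(overlaps))], abs=0.005)

    def test_unit_detection_gives_unit_factor(self):
        cell = typical_cell()
        z, a = axial_cross_section(cell)
        D = DetectionProfile(np.linspace(-2, 2, 11), np.ones(11), 2.3, 1e9)
        assert defocus_correction_factor((z, a), D) == pytest.approx(1.0)

    def test_slab_factor_matches_quadrature(self):
        # D = indicator(|z| <= 0.25) on a round r = 0.5 cell
        cell = typical_cell()
        z, a = axial_cross_section(cell, n_points=4001)
        zd, Dv = box_profile(-0.25, 0.25, n=8001)
        D = DetectionProfile(zd, Dv, 2.3, 1e9)
        expected = np.trapezoid(a, z) / np.trapezoid(
            a * ((z >= -0.25) & (z <= 0.25)), z
        )
        assert defocus_correction_factor((z, a), D) == pytest.approx(
            expected, rel=1e-3
        )
        assert expected > 1

    def test_disjoint_supports_raise(self):
        cell = typical_cell()
        z, a = axial_cross_section(cell)
        D = DetectionProfile(np.linspace(5, 6, 11), np.ones(11), 2.3, 1e9)
        with pytest.raises(ValueError):
            defocus_correction_factor((z, a), D)

    def test_correction_reduces_mean_bias(self):
        cell = typical_cell()
        zd = np.linspace(-1.0, 1.0, 81)
        D = DetectionProfile(zd, ((np.abs(zd) <= 0.25) * 1.0), 2.3, 1e9)
        df = undercount_curve([5], cell=cell, n_trials=800, rng=5, correction=D)
        n_true = 5
        bias_naive = abs(df["mean_counted"].iloc[0] - n_true)
        bias_corr = abs(df["mean_corrected"].iloc[0] - n_true)
        assert bias_corr < bias_naive
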