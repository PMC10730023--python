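"""Radial profiling, phantom calibration and LUT inversion."""

import numpy as np
import pytest

from speckleflow.forward_models import OpticalProperties, diffuse_reflectance
from speckleflow.lut_engine import build_lut
from speckleflow.srdrs import (AlignmentError, CalibrationError,
                               CalibrationReference, GeometryError,
                               ProbeGeometry, RadialProfile, UndefinedR2Error,
                               calibrate_profile, invert_properties,
                               r_squared, radial_profile, scale_factor)


def _exp_frame(geometry, shape=(256, 256), offset=10.0):
    rho = geometry.rho_map(shape)
    return np.exp(-np.clip(rho, 0.01, None)) + offset


class TestRadialProfile:
    def test_reproduces_radial_function_after_dark_subtraction(self, geometry):
        frame = _exp_frame(geometry)
        dark = np.full(frame.shape, 10.0)
        prof = radial_profile(frame, geometry, dark)
        np.testing.assert_allclose(prof.mean_intensity,
                                   np.exp(-prof.rho_centers), rtol=0.01)
        assert np.all(np.diff(prof.rho_centers) > 0)
        assert np.all(prof.pixel_counts > 0)

    def test_frame_equal_to_dark_gives_zero_profile(self, geometry):
        frame = np.full((256, 256), 7.0)
        prof = radial_profile(frame, geometry, frame)
        assert np.all(prof.mean_intensity == 0)

    def test_pixel_bin_assignment(self):
        """A pixel 35 px from the source at 0.1 mm/px lands in the
        [3.5, 3.6) mm bin."""
        geom = ProbeGeometry(source_px=(0.0, 0.0), pixel_pitch=0.1,
                             rho_min=3.0, rho_max=5.0, bin_width=0.1)
        frame = np.zeros((60, 60))
        frame[0, 35] = 100.0
        prof = radial_profile(frame, geom)
        bin_of_pixel = prof.rho_centers[prof.mean_intensity > 0]
        assert len(bin_of_pixel) == 1
        assert 3.5 <= bin_of_pixel[0] < 3.6

    def test_annulus_outside_frame_raises(self):
        geom = ProbeGeometry(source_px=(5.0, 5.0), pixel_pitch=0.01,
                             rho_min=3.0, rho_max=10.0)
        with pytest.raises(GeometryError):
            radial_profile(np.ones((10, 10)), geom)

    def test_mismatched_dark_shape_raises(self, geometry):
        with pytest.raises(ValueError):
            radial_profile(np.ones((64, 64)), geometry, np.ones((32, 32)))


@pytest.fixture()
def phantom_setup(geometry, small_lut):
    """Calibration phantom whose measured profile is a scaled LUT node."""
    i, j = 4, 8
    props = OpticalProperties(mua=small_lut.mua_grid[i],
                              musp=small_lut.musp_grid[j], wavelength=660.0)
    theory = np.interp(np.arange(3.05, 8.0, 0.1), small_lut.rho_grid,
                       small_lut.curve_at_node(i, j))
    centers = np.arange(3.05, 8.0, 0.1)
    return props, centers, theory


class TestScaleFactor:
    def _calref(self, props, centers, measured):
        prof = RadialProfile(rho_centers=centers, mean_intensity=measured,
                             pixel_counts=np.full(centers.size, 50),
                             channel="L660")
        return CalibrationReference(phantom_props={"L660": props},
                                    measured_profile={"L660": prof})

    def test_identity_when_measured_equals_theory(self, phantom_setup, small_lut):
        props, centers, theory = phantom_setup
        sv = scale_factor(small_lut, self._calref(props, centers, theory),
                          "L660")
        np.testing.assert_allclose(sv, 1.0, rtol=1e-12)

    def test_half_when_measured_is_double(self, phantom_setup, small_lut):
        props, centers, theory = phantom_setup
        sv = scale_factor(small_lut,
                          self._calref(props, centers, 2.0 * theory), "L660")
        np.testing.assert_allclose(sv, 0.5, rtol=1e-12)

    def test_zero_bin_raises_calibration_error(self, phantom_setup, small_lut):
        props, centers, theory = phantom_setup
        bad = theory.copy()
        bad[10] = 0.0
        with pytest.raises(CalibrationError):
            scale_factor(small_lut, self._calref(props, centers, bad), "L660")


class TestCalibrateProfile:
    def test_unit_scale_leaves_profile_unchanged(self, phantom_setup):
        _, centers, theory = phantom_setup
        prof = RadialProfile(centers, theory, np.full(centers.size, 9))
        np.testing.assert_array_equal(
            calibrate_profile(prof, np.ones(centers.size)), theory)

    def test_grid_mismatch_raises(self, phantom_setup):
        _, centers, theory = phantom_setup
        prof = RadialProfile(centers, theory, np.full(centers.size, 9))
        with pytest.raises(AlignmentError):
            calibrate_profile(prof, np.ones(centers.size - 1))


class TestRSquared:
    def test_identical_curves_give_exactly_one(self):
        y = diffuse_reflectance(np.linspace(3, 10, 30),
                                OpticalProperties(mua=0.02, musp=1.2))
        assert r_squared(y, y) == 1.0

    def test_constant_multiplicative_offset(self):
        """A 1.05x copy leaves a constant log offset whose R^2 follows
        from direct evaluation of the definition (computed independently
        here from the raw sums of squares)."""
        rho = np.linspace(3, 10, 30)
        y_th = diffuse_reflectance(rho, OpticalProperties(mua=0.02, musp=1.2))
        y_meas = 1.05 * y_th
        lt = np.log(y_th)
        expected = 1.0 - (30 * np.log(1.05) ** 2) / np.sum((lt - lt.mean()) ** 2)
        assert r_squared(y_meas, y_th) == pytest.approx(expected, rel=1e-12)
        assert r_squared(y_meas, y_th) < 1.0

    def test_permutation_strictly_below_one(self):
        rho = np.linspace(3, 10, 30)
        y = diffuse_reflectance(rho, OpticalProperties(mua=0.02, musp=1.2))
        rng = np.random.default_rng(0)
        assert r_squared(rng.permutation(y), y) < 1.0

    def test_zero_variance_theory_raises(self):
        with pytest.raises(UndefinedR2Error):
            r_squared(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))


class TestInvertProperties:
    def test_node_curve_recovered_exactly(self, default_lut):
        i, j = 4, 14
        curve = default_lut.curve_at_node(i, j)
        res = invert_properties(curve, default_lut, 0.98)
        assert res.props.mua == default_lut.mua_grid[i]
        assert res.props.musp == default_lut.musp_grid[j]
        assert res.n_candidates_averaged == 1
        assert res.best_r2 == 1.0
        assert not res.fallback_flag

    def test_two_candidates_average_arithmetically(self, default_lut):
        """A curve equidistant (in log misfit) between two adjacent nodes
        averages their property pairs."""
        a = np.log(default_lut.curve_at_node(4, 14))
        b = np.log(default_lut.curve_at_node(5, 15))
        curve = np.exp(0.5 * (a + b))
        res = invert_properties(curve, default_lut, 0.98)
        assert res.n_candidates_averaged == 2
        assert res.props.mua == pytest.approx(
            0.5 * (default_lut.mua_grid[4] + default_lut.mua_grid[5]))
        assert res.props.musp == pytest.approx(
            0.5 * (default_lut.musp_grid[14] + default_lut.musp_grid[15]))

    def test_fallback_flag_when_nothing_passes(self, default_lut):
        curve = default_lut.curve_at_node(10, 30)
        noisy = curve * np.exp(0.5 * np.sin(np.arange(curve.size)))
        res = invert_properties(noisy, default_lut, 0.9999)
        assert res.fallback_flag
        assert res.n_candidates_averaged == 1

    def test_raising_threshold_never_adds_candidates(self, default_lut):
        rng = np.random.default_rng(3)
        curve = diffuse_reflectance(
            default_lut.rho_grid, OpticalProperties(mua=0.05, musp=1.3))
        noisy = curve * (1 + 0.02 * rng.standard_normal(curve.size))
        counts = [invert_properties(noisy, default_lut, thr,
                                    best_margin_factor=None).n_candidates_averaged
                  for thr in (0.9, 0.95, 0.98, 0.995)]
        assert counts == sorted(counts, reverse=True)

    def test_gain_invariance_through_calibration(self, geometry, small_lut):
        """A common gain on sample and calibration frames cancels in the
        scale factor, leaving the inversion unchanged."""
        i, j = 4, 8
        props = OpticalProperties(mua=small_lut.mua_grid[i],
                                  musp=small_lut.musp_grid[j])
        rho = geometry.rho_map((256, 256))
        base = diffuse_reflectance(np.clip(rho, 0.02, None), props)
        results = []
        for gain in (1e5, 7e5):
            frame = gain * base
            prof = radial_profile(frame, geometry, None, channel="L660")
            calref = CalibrationReference(
                phantom_props={"L660": props},
                measured_profile={"L660": prof})
            lut = build_lut(small_lut.mua_grid, small_lut.musp_grid,
                            prof.rho_centers)
            sv = scale_factor(lut, calref, "L660")
            curve = calibrate_profile(prof, sv)
            results.append(invert_properties(curve, lut, 0.98))
        assert results[0].props.mua == results[1].props.mua
        assert results[0].props.musp == results[1].props.musp
        # closure: the phantom-as-sample returns the phantom's properties
        assert results[0].props.mua == props.mua
        assert results[0].props.musp == props.musp

    def test_recovery_degrades_gracefully_with_noise(self, default_lut):
        rng = np.random.default_rng(12)
        truths = [(rng.uniform(0.02, 0.25), rng.uniform(0.6, 2.5))
                  for _ in range(12)]
        med_errs = []
        for noise in (0.0, 0.01, 0.05):
            errs = []
            for mua, musp in truths:
                curve = diffuse_reflectance(
                    default_lut.rho_grid,
                    OpticalProperties(mua=mua, musp=musp))
                noisy = curve * (1 + noise * rng.standard_normal(curve.size))
                res = invert_properties(noisy, default_lut, 0.98)
                errs.append(abs(res.props.mua - mua) / mua +
                            abs(res.props.musp - musp) / musp)
            med_errs.append(np.median(errs))
        assert med_errs[0] <= med_errs[2]
        assert med_errs[1] <= med_errs[2]

    def test_empty_curve_alignment_error(self, default_lut):
        with pytest.raises(AlignmentError):
            invert_properties(np.ones(5), default_lut, 0.98)
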