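"""Speckle-contrast estimation and the SPG (1/K^2) trace."""

import numpy as np
import pytest

from speckleflow.lsi import (SpeckleContrastMap, correct_window_bias,
                             roi_mask, speckle_contrast_map, spg_trace)
from speckleflow.srdrs import GeometryError, ProbeGeometry


class TestSpeckleContrastMap:
    def test_constant_frame_has_zero_contrast(self):
        m = speckle_contrast_map(np.full((64, 64), 100.0))
        assert np.all(m.K[m.valid_mask] == 0)
        assert m.valid_mask.sum() == (64 - 6) ** 2

    def test_border_pixels_masked_invalid(self):
        m = speckle_contrast_map(np.ones((32, 32)))
        assert not m.valid_mask[0].any() and not m.valid_mask[-1].any()
        assert not m.valid_mask[:, :3].any()

    def test_fully_developed_speckle_contrast_near_unity(self):
        """i.i.d. exponential intensities: mean 7x7 K in [0.94, 1.00]
        (finite-window estimator bias keeps it just below 1)."""
        rng = np.random.default_rng(21)
        frame = rng.exponential(120.0, size=(200, 200))
        m = speckle_contrast_map(frame)
        kbar = m.K[m.valid_mask].mean()
        assert 0.94 <= kbar <= 1.00

    def test_gamma_shape4_speckle_contrast_half(self):
        """CV of gamma(k) is 1/sqrt(k): shape 4 gives K = 0.5 within 2%."""
        rng = np.random.default_rng(22)
        frame = rng.gamma(4.0, 30.0, size=(220, 220))
        m = speckle_contrast_map(frame)
        assert m.K[m.valid_mask].mean() == pytest.approx(0.5, rel=0.02)

    def test_estimator_converges_to_analytic_cv(self):
        """Mean windowed K approaches 1/sqrt(shape) as the frame grows,
        for three gamma shapes."""
        rng = np.random.default_rng(23)
        for shape in (2.0, 8.0, 25.0):
            errs = []
            for side in (50, 400):
                f = rng.gamma(shape, 10.0, size=(side, side))
                m = speckle_contrast_map(f)
                errs.append(abs(m.K[m.valid_mask].mean() * np.sqrt(shape) - 1))
            assert errs[-1] < 0.02

    def test_window_bias_correction_tightens_estimate(self):
        rng = np.random.default_rng(24)
        frame = rng.gamma(16.0, 10.0, size=(400, 400))
        m = speckle_contrast_map(frame)
        raw = m.K[m.valid_mask].mean()
        corrected = correct_window_bias(raw)
        assert abs(corrected - 0.25) < abs(raw - 0.25)

    def test_all_zero_frame_warns_and_masks_all(self):
        with pytest.warns(RuntimeWarning):
            m = speckle_contrast_map(np.zeros((32, 32)))
        assert not m.valid_mask.any()

    def test_frame_smaller_than_window_raises(self):
        with pytest.raises(ValueError):
            speckle_contrast_map(np.ones((5, 5)))


class TestRoiMask:
    GEOM = ProbeGeometry(source_px=(0.0, 0.0), pixel_pitch=0.1,
                         rho_min=3.0, rho_max=10.0)

    def test_interval_is_closed_on_both_ends(self):
        mask = roi_mask(self.GEOM, (60, 60))
        assert mask[0, 35]        # rho = 3.5 mm inside
        assert not mask[0, 30]    # rho = 3.0 mm below the 3.1 mm bound
        assert mask[0, 44]        # rho = 4.4 mm: closed upper bound
        assert not mask[0, 45]

    def test_empty_roi_raises(self):
        geom = ProbeGeometry(source_px=(0.0, 0.0), pixel_pitch=0.001)
        with pytest.raises(GeometryError):
            roi_mask(geom, (10, 10))


def _uniform_map(k, shape=(40, 40), t=0.0):
    valid = np.zeros(shape, bool)
    valid[3:-3, 3:-3] = True
    return SpeckleContrastMap(K=np.full(shape, k), valid_mask=valid,
                              timestamp=t)


class TestSpgTrace:
    MASK = np.ones((40, 40), bool)

    def test_uniform_contrast_arithmetic(self):
        trace = spg_trace([_uniform_map(0.5), _uniform_map(1.0, t=1.0)],
                          self.MASK)
        np.testing.assert_allclose(trace.spg, [4.0, 1.0])
        np.testing.assert_allclose(trace.t, [0.0, 1.0])

    def test_zero_contrast_frame_flagged_not_infinite(self):
        trace = spg_trace([_uniform_map(0.0)], self.MASK)
        assert trace.flags[0]
        assert np.isnan(trace.spg[0])

    def test_anti_monotone_in_contrast(self):
        rng = np.random.default_rng(5)
        k1 = 0.3 + 0.1 * rng.random((40, 40))
        k2 = k1 + 0.2
        valid = np.zeros((40, 40), bool)
        valid[3:-3, 3:-3] = True
        trace = spg_trace([SpeckleContrastMap(k1, valid, 0.0),
                           SpeckleContrastMap(k2, valid, 1.0)], self.MASK)
        assert trace.spg[0] > trace.spg[1]

    def test_translation_invariance(self):
        """Shifting frame content and mask together leaves SPG unchanged."""
        rng = np.random.default_rng(6)
        frame = rng.gamma(4.0, 10.0, size=(80, 80))
        mask = np.zeros((80, 80), bool)
        mask[20:40, 20:40] = True
        shifted_frame = np.roll(frame, (7, 11), axis=(0, 1))
        shifted_mask = np.roll(mask, (7, 11), axis=(0, 1))
        t1 = spg_trace([speckle_contrast_map(frame)], mask)
        t2 = spg_trace([speckle_contrast_map(shifted_frame)], shifted_mask)
        assert t1.spg[0] == pytest.approx(t2.spg[0], rel=1e-10)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            spg_trace([], self.MASK)


def test_pulsatile_flow_appears_at_cardiac_frequency():
    """A 1 Hz sinusoidal Db modulation produces a 1 Hz periodogram peak
    in the rendered SPG trace."""
    from speckleflow.lsi import flat_field
    from speckleflow.srdrs import ProbeGeometry
    from speckleflow.synthetic import constant_scene, render_frame

    geom = ProbeGeometry(source_px=(64.0, 14.0), pixel_pitch=0.05,
                         rho_min=3.0, rho_max=5.0)
    scene = constant_scene(duration=4.0, seed=9, pulse=True,
                           shot_noise=False, frame_shape=(128, 160),
                           geometry=geom)
    fs = 67.5
    times = np.arange(0.0, 4.0, 1 / fs)
    frames = np.stack([render_frame(scene, "V850", t) for t in times])
    flat = flat_field(frames - scene.dark_offset)
    mask = roi_mask(geom, frames.shape[1:])
    maps = [speckle_contrast_map((f - scene.dark_offset) / flat, timestamp=t)
            for f, t in zip(frames, times)]
    trace = spg_trace(maps, mask)
    sig = trace.spg - trace.spg.mean()
    freqs = np.fft.rfftfreq(sig.size, 1 / fs)
    power = np.abs(np.fft.rfft(sig)) ** 2
    peak = freqs[1:][np.argmax(power[1:])]
    assert peak == pytest.approx(1.0, abs=0.3)
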