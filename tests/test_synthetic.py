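"""Synthetic scene generation and frame rendering."""

import numpy as np
import pytest

from speckleflow.lsi import speckle_contrast_map
from speckleflow.srdrs import ProbeGeometry, radial_profile
from speckleflow.synthetic import (SCHEDULE, BaselineScene, constant_scene,
                                   load_sequence, make_protocol, render_frame,
                                   render_dark_frame, render_sequence,
                                   save_sequence, scene_from_protocol)
from speckleflow.forward_models import OpticalProperties, diffuse_reflectance


class TestProtocols:
    def test_arterial_protocol(self):
        p = make_protocol("arterial")
        assert p.total_duration == 360.0
        assert max(pr for _, pr in p.segments) == 220.0
        assert p.segments == ((120.0, 0.0), (120.0, 220.0), (120.0, 0.0))

    def test_venous_protocol(self):
        p = make_protocol("venous")
        assert len(p.segments) == 7
        assert [pr for _, pr in p.segments] == [0, 20, 40, 60, 80, 100, 0]
        assert p.total_duration == 480.0

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            make_protocol("capillary")


class TestSceneFromProtocol:
    def test_zero_pressure_protocol_is_constant_baseline(self):
        from speckleflow.synthetic import ProtocolSpec
        base = BaselineScene()
        scene = scene_from_protocol(ProtocolSpec("venous", ((30.0, 0.0),)),
                                    base)
        np.testing.assert_allclose(scene.HbO2_t, base.HbO2)
        np.testing.assert_allclose(scene.Hb_t, base.Hb)
        np.testing.assert_allclose(scene.Db_t, base.Db)

    def test_venous_flow_monotone_down_across_steps(self):
        scene = scene_from_protocol(make_protocol("venous"))
        # sample late in each pressure step, past the smoothing transient
        step_ends = [110, 170, 230, 290, 350, 410]
        db = [scene.Db_t[np.searchsorted(scene.t_grid, t)] for t in step_ends]
        assert np.all(np.diff(db) < 0)

    def test_venous_hbt_rises_with_pressure(self):
        scene = scene_from_protocol(make_protocol("venous"))
        i0 = np.searchsorted(scene.t_grid, 110)
        i5 = np.searchsorted(scene.t_grid, 410)
        hbt = scene.HbO2_t + scene.Hb_t
        assert hbt[i5] > hbt[i0]

    def test_arterial_flow_collapses_below_ten_percent(self):
        scene = scene_from_protocol(make_protocol("arterial"))
        mid_occl = np.searchsorted(scene.t_grid, 200)
        assert scene.Db_t[mid_occl] < 0.1 * BaselineScene().Db

    def test_arterial_conserves_total_hemoglobin(self):
        scene = scene_from_protocol(make_protocol("arterial"))
        hbt = scene.HbO2_t + scene.Hb_t
        np.testing.assert_allclose(hbt, hbt[0], rtol=1e-6)


class TestRenderFrame:
    def test_dark_render_cancels_after_subtraction(self, geometry):
        scene = constant_scene(duration=1.0, seed=3, gain=0.0,
                               geometry=geometry)
        frame = render_frame(scene, "L660", 0.5)
        dark = render_dark_frame(scene)
        prof = radial_profile(frame, geometry,
                              np.full(scene.frame_shape, scene.dark_offset))
        # Poisson noise around the offset only; means stay near zero
        assert np.abs(prof.mean_intensity).max() < 2.0
        assert dark.mean() == pytest.approx(scene.dark_offset, rel=0.05)

    def test_noiseless_led_frame_reproduces_forward_curve(self, geometry):
        scene = constant_scene(duration=1.0, seed=3, shot_noise=False,
                               geometry=geometry)
        frame = render_frame(scene, "L660", 0.2)
        prof = radial_profile(frame, geometry,
                              np.full(scene.frame_shape, scene.dark_offset))
        expected = scene.gain * diffuse_reflectance(
            prof.rho_centers, scene.props_at(660.0, 0.2))
        np.testing.assert_allclose(prof.mean_intensity, expected, rtol=0.01)

    def test_static_vcsel_frame_is_fully_developed_speckle(self, geometry):
        """Db = 0 with beta = 1: frame-wide 7x7 contrast in [0.94, 1.0]."""
        scene = constant_scene(
            BaselineScene(Db=0.0), duration=1.0, seed=4, shot_noise=False,
            geometry=geometry)
        frame = render_frame(scene, "V850", 0.5)
        rho = geometry.rho_map(scene.frame_shape)
        sub = frame[(rho > 3.3) & (rho < 3.6)]
        k = sub.std(ddof=1) / sub.mean()  # narrow annulus: mean ~constant
        assert 0.90 <= k <= 1.05
        m = speckle_contrast_map(frame / (frame.mean() or 1.0))
        assert m.valid_mask.any()

    def test_unknown_channel_rejected(self, geometry):
        scene = constant_scene(duration=1.0, geometry=geometry)
        with pytest.raises(ValueError):
            render_frame(scene, "L520", 0.1)
        with pytest.raises(ValueError):
            render_frame(scene, "L660", 5.0)  # outside support


class TestRenderSequence:
    def test_twelve_frames_follow_schedule(self, geometry):
        scene = constant_scene(duration=1.0, seed=5, geometry=geometry,
                               frame_shape=(64, 64))
        seq = render_sequence(scene, duration=12 / 135.0)
        assert seq.channels == list(SCHEDULE) * 3
        assert seq.channels.count("V850") == 6
        assert seq.channels.count("L660") == 3
        assert seq.channels.count("L740") == 3

    def test_one_second_gives_135_frames_67_vcsel(self, geometry):
        scene = constant_scene(duration=1.0, seed=5, geometry=geometry,
                               frame_shape=(64, 64))
        seq = render_sequence(scene, duration=1.0)
        assert len(seq) == 135
        assert abs(seq.channels.count("V850") - 67) <= 1

    def test_same_seed_is_bitwise_reproducible(self, geometry):
        scene = constant_scene(duration=1.0, seed=6, geometry=geometry,
                               frame_shape=(64, 64))
        a = render_sequence(scene, duration=0.2)
        b = render_sequence(scene, duration=0.2)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_disk_round_trip(self, geometry, tmp_path):
        scene = constant_scene(duration=1.0, seed=7, geometry=geometry,
                               frame_shape=(64, 64))
        seq = render_sequence(scene, duration=0.1)
        path = tmp_path / "seq.tif"
        save_sequence(seq, path)
        loaded = load_sequence(path)
        assert loaded.channels == seq.channels
        np.testing.assert_allclose(loaded.timestamps, seq.timestamps)
        np.testing.assert_allclose(loaded.frames, np.round(seq.frames))
        assert loaded.geometry.pixel_pitch == seq.geometry.pixel_pitch
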