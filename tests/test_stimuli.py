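"""Stimulus generator: determinism, photometry, kinematics, symmetry."""

import logging

import numpy as np
import pytest

from flymotion.stimuli import (
    GREY_LEVELS,
    StimulusSpec,
    clutter_texture,
    render,
    render_clutter_background,
    render_depth,
    render_translation,
)


def bar_spec(**kw):
    base = dict(
        field_width=160, field_height=90, duration=30, target_kind="bar",
        target_size=(10, 40), target_grey=255, target_velocity=27.0,
        velocity_axis="horizontal", background_kind="uniform", background_grey=0,
    )
    base.update(kw)
    return StimulusSpec(**base)


class TestSpecValidation:
    def test_rejects_zero_fps(self):
        with pytest.raises(ValueError):
            bar_spec(fps=0)

    def test_rejects_target_larger_than_field(self):
        with pytest.raises(ValueError):
            render_translation(bar_spec(target_size=(200, 40)))

    @pytest.mark.parametrize(
        "kw",
        [dict(target_kind="blob"), dict(velocity_axis="diagonal"),
         dict(background_kind="photo"), dict(duration=0), dict(target_grey=300)],
    )
    def test_rejects_invalid_fields(self, kw):
        with pytest.raises(ValueError):
            bar_spec(**kw)

    def test_roundtrips_through_yaml(self, tmp_path):
        spec = bar_spec(background_kind="procedural_clutter", texture_seed=3)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(str(p))
        assert StimulusSpec.from_yaml(str(p)) == spec

    def test_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            StimulusSpec.from_dict({"colour": "red"})


class TestDeterminismAndPhotometry:
    def test_identical_spec_renders_bit_identical(self):
        spec = bar_spec(background_kind="procedural_clutter",
                        background_velocity=-20, texture_seed=11)
        a, b = render(spec), render(spec)
        assert a.frames.dtype == np.uint8
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_different_seeds_differ(self):
        t1 = clutter_texture(40, 60, seed=1)
        t2 = clutter_texture(40, 60, seed=2)
        assert not np.array_equal(t1, t2)
        np.testing.assert_array_equal(t1, clutter_texture(40, 60, seed=1))

    def test_pixel_values_within_bounds(self):
        stim = render(bar_spec(background_kind="procedural_clutter",
                               background_velocity=-40, texture_seed=5))
        assert stim.frames.min() >= 0 and stim.frames.max() <= 255

    def test_sequence_shape_matches_spec(self):
        spec = bar_spec(duration=17)
        stim = render(spec)
        assert stim.frames.shape == (17, spec.field_height, spec.field_width)


class TestTranslationKinematics:
    def test_zero_velocity_freezes_every_frame(self):
        stim = render(bar_spec(target_velocity=0.0))
        assert (stim.frames == stim.frames[0]).all()

    def test_centroid_follows_analytic_trajectory(self):
        # 9 deg/s at 0.25 deg/px, 30 fps -> 1.2 px/frame
        spec = bar_spec(target_velocity=9.0, duration=40)
        assert spec.px_per_frame == pytest.approx(1.2)
        stim = render(spec)
        for t in (0, 10, 25, 39):
            ys, xs = np.nonzero(stim.frames[t] == 255)
            measured = xs.mean()
            assert measured == pytest.approx(stim.target_centres[t, 0], abs=1.0)
        total = stim.target_centres[-1, 0] - stim.target_centres[0, 0]
        assert total == pytest.approx(1.2 * 39)

    def test_vertical_axis_moves_rows(self):
        spec = bar_spec(velocity_axis="vertical", target_velocity=18.0, duration=20,
                        target_size=(40, 10))
        stim = render(spec)
        ys0 = np.nonzero(stim.frames[0] == 255)[0]
        ys1 = np.nonzero(stim.frames[10] == 255)[0]
        assert ys1.mean() > ys0.mean()

    def test_inside_flag_tracks_field_exit(self):
        spec = bar_spec(duration=60)  # 3.6 px/frame exits the 160 px field
        stim = render(spec)
        assert stim.inside[0]
        assert not stim.inside[-1]

    def test_leftward_render_mirrors_rightward(self):
        # velocities with fractional part 0.6 px/frame avoid exact .5 rounding ties
        right = bar_spec(target_velocity=27.0, duration=30)
        left = right.mirrored_horizontal()
        a, b = render(right), render(left)
        np.testing.assert_array_equal(a.frames[:, :, ::-1], b.frames)


class TestDepthMotion:
    def disc_spec(self, **kw):
        base = dict(field_width=120, field_height=90, duration=30,
                    target_kind="disc", target_size=(10, 10), target_grey=0,
                    target_velocity=4.5, velocity_axis="depth",
                    background_kind="uniform", background_grey=128)
        base.update(kw)
        return StimulusSpec(**base)

    def test_disc_grows_when_approaching(self):
        stim = render(self.disc_spec())
        areas = [(f == 0).sum() for f in stim.frames]
        assert areas[-1] > areas[0] > 0
        assert np.all(np.diff(areas) >= 0)

    def test_zero_rate_keeps_disc_static(self):
        stim = render(self.disc_spec(target_velocity=0.0))
        assert (stim.frames == stim.frames[0]).all()

    def test_every_frame_mirror_symmetric(self):
        stim = render(self.disc_spec())
        np.testing.assert_array_equal(stim.frames, stim.frames[:, :, ::-1])
        np.testing.assert_array_equal(stim.frames, stim.frames[:, ::-1, :])

    def test_radius_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            stim = render_depth(self.disc_spec(target_velocity=45.0, duration=40))
        assert "clamped" in caplog.text
        # clamped disc never exceeds half the smaller field dimension
        assert (stim.frames[-1] == 0).sum() <= np.pi * (45**2) * 1.1


class TestClutterBackground:
    def test_scroll_matches_phase_correlation(self):
        # -20 deg/s at 0.25 deg/px, 30 fps -> -2.667 px/frame
        frames = render_clutter_background(
            width=240, height=60, texture_seed=9, background_velocity=-20.0,
            degrees_per_pixel=0.25, fps=30.0, duration=16,
        )
        v_px = -20.0 / (0.25 * 30.0)
        for t in (3, 9, 15):
            f0 = frames[0].astype(float) - frames[0].mean()
            ft = frames[t].astype(float) - frames[t].mean()
            xc = np.fft.ifft(
                np.fft.fft(f0, axis=1) * np.conj(np.fft.fft(ft, axis=1)), axis=1
            ).real.sum(axis=0)
            lag = np.argmax(xc)
            expected = (-round(v_px * t)) % 240
            assert lag == expected

    def test_zero_velocity_static_texture(self):
        frames = render_clutter_background(100, 40, 2, 0.0, 0.25, 30.0, 5)
        assert (frames == frames[0]).all()

    def test_contains_low_contrast_pockets(self):
        tex = clutter_texture(180, 700, seed=7).astype(float)
        # local std over 40 px tiles: the darkest-contrast tile is well below
        # the brightest, emulating shadowed regions
        stds = [tex[i:i + 40, j:j + 40].std()
                for i in range(0, 140, 40) for j in range(0, 660, 40)]
        assert min(stds) < 0.3 * max(stds)

    def test_named_grey_levels_bracket_texture_mean(self):
        tex = clutter_texture(90, 200, seed=4)
        assert GREY_LEVELS["dark"] < tex.mean() < GREY_LEVELS["white"]
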