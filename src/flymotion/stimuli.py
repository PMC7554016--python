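"""Synthetic visual stimuli: translating bars/squares, looming discs, and
procedurally cluttered moving backgrounds.

All sequences are deterministic functions of their spec (including the
texture seed): identical specs render bit-identical uint8 frame stacks of
shape (T, R, C) with values in [0, 255].  Angular quantities are converted
to pixels through a single calibration scalar ``degrees_per_pixel`` (default
0.25 deg/px), so px/frame = velocity / (degrees_per_pixel * fps).

Targets are drawn with hard edges at sub-pixel positions rounded to the
nearest pixel — the model is edge-driven and the reference stimuli are
hard-edged — and target pixels replace background pixels.  The cluttered
background is a seeded, band-limited procedural texture (a stand-in for
natural photographs) that scrolls horizontally with periodic wrap and
contains low-contrast "shadow" pockets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .params import ModelParams

__all__ = [
    "StimulusSpec",
    "Stimulus",
    "GREY_LEVELS",
    "clutter_texture",
    "render_clutter_background",
    "render_translation",
    "render_depth",
    "render",
]

log = logging.getLogger(__name__)

#: Named grey levels of the translating targets (0-255 luminance).
GREY_LEVELS = {"white": 255, "moderate": 160, "dark": 20}


@dataclass
class StimulusSpec:
    """Declarative description of one synthetic sequence.

    Velocities are signed angular velocities in deg/s: positive is rightward
    (horizontal axis), downward (vertical axis) or expanding (depth axis).
    ``target_size`` is (width, height) in px; for the depth axis the width is
    interpreted as the starting disc diameter.  ``target_start`` optionally
    fixes the target's top-left corner (x, y) at frame 0 in float px;
    otherwise the target starts flush against the field edge it moves away
    from, centred on the orthogonal axis.
    """

    field_width: int = 320
    field_height: int = 180
    fps: float = 30.0
    degrees_per_pixel: float = 0.25
    duration: int = 100
    target_kind: str = "bar"  # bar | square | disc | none
    target_size: tuple[int, int] = (25, 120)
    target_grey: float = 255
    target_velocity: float = 27.0
    velocity_axis: str = "horizontal"  # horizontal | vertical | depth
    background_kind: str = "uniform"  # uniform | procedural_clutter
    background_grey: float = 128
    background_velocity: float = 0.0
    texture_seed: int = 0
    target_start: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration < 1:
            raise ValueError("duration must be at least one frame")
        if self.field_width < 1 or self.field_height < 1:
            raise ValueError("field must be at least 1x1 px")
        if self.target_kind not in ("bar", "square", "disc", "none"):
            raise ValueError(f"unknown target_kind {self.target_kind!r}")
        if self.velocity_axis not in ("horizontal", "vertical", "depth"):
            raise ValueError(f"unknown velocity_axis {self.velocity_axis!r}")
        if self.background_kind not in ("uniform", "procedural_clutter"):
            raise ValueError(f"unknown background_kind {self.background_kind!r}")
        if not (0 <= self.target_grey <= 255 and 0 <= self.background_grey <= 255):
            raise ValueError("grey levels must lie in [0, 255]")

    @property
    def px_per_frame(self) -> float:
        """Target displacement in px/frame implied by the calibration."""
        return self.target_velocity / (self.degrees_per_pixel * self.fps)

    @property
    def background_px_per_frame(self) -> float:
        return self.background_velocity / (self.degrees_per_pixel * self.fps)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_size"] = list(self.target_size)
        if self.target_start is not None:
            d["target_start"] = list(self.target_start)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown stimulus keys: {sorted(unknown)}")
        d = dict(d)
        if "target_size" in d:
            d["target_size"] = tuple(d["target_size"])
        if d.get("target_start") is not None:
            d["target_start"] = tuple(d["target_start"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "StimulusSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def mirrored_horizontal(self) -> "StimulusSpec":
        """Spec whose render is the horizontal mirror of this one's
        (uniform backgrounds only; clutter textures are not symmetric)."""
        start = None
        if self.target_start is not None:
            x, y = self.target_start
            start = (self.field_width - self.target_size[0] - x, y)
        v = -self.target_velocity if self.velocity_axis == "horizontal" else self.target_velocity
        return replace(self, target_velocity=v, target_start=start)


@dataclass
class Stimulus:
    """A rendered sequence plus its kinematic ground truth.

    ``target_centres`` holds the analytic (un-rounded) target centre (x, y)
    per frame, or NaN where no target exists; ``inside`` flags the frames in
    which the target lies fully inside the field (the "crossing window" over
    which response statistics are taken).
    """

    frames: np.ndarray
    spec: StimulusSpec
    target_centres: np.ndarray
    inside: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)


def _round_px(x: float) -> int:
    # floor(x + 0.5): plain half-up rounding, stable across platforms
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

def clutter_texture(height: int, width: int, seed: int) -> np.ndarray:
    """Seeded band-limited texture emulating a natural cluttered scene.

    Multi-octave smoothed Gaussian noise (periodic in x so the scroll can
    wrap) gives broad spatial-frequency content with amplitude increasing
    with scale, emulating the low-frequency dominance of natural scenes;
    the finest octave (12 px) is kept coarser than the centre-surround
    passband, as in optically blurred natural imagery.  Two further smooth
    fields modulate the local mean (bright vs shadowed regions, ~[40, 170])
    and the local contrast (down to ~20% in "shadow" pockets).  Values are
    quantised to uint8 in [0, 255].
    """
    rng = np.random.default_rng(seed)
    base = np.zeros((height, width))
    for sigma in (12, 24, 48):
        base += sigma * gaussian_filter(
            rng.standard_normal((height, width)), sigma, mode="wrap"
        )
    base /= base.std()

    def smooth_unit(sigma: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((height, width)), sigma, mode="wrap")
        lo, hi = f.min(), f.max()
        return (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)

    mean_field = 40.0 + 130.0 * smooth_unit(48)
    contrast_field = 0.2 + 0.8 * smooth_unit(40)
    tex = mean_field + 45.0 * contrast_field * base
    return np.clip(np.rint(tex), 0, 255).astype(np.uint8)


def render_clutter_background(
    width: int,
    height: int,
    texture_seed: int,
    background_velocity: float,
    degrees_per_pixel: float,
    fps: float,
    duration: int,
) -> np.ndarray:
    """Scroll the seeded texture horizontally with periodic wrap.

    The per-frame offset is the cumulative analytic displacement
    ``background_velocity / (degrees_per_pixel * fps) * t`` rounded to the
    nearest pixel, so the long-run scroll speed is exact even when the
    per-frame displacement is fractional.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    tex = clutter_texture(height, width, texture_seed)
    v_px = background_velocity / (degrees_per_pixel * fps)
    frames = np.empty((duration, height, width), dtype=np.uint8)
    for t in range(duration):
        shift = _round_px(v_px * t)
        frames[t] = np.roll(tex, shift, axis=1)
    return frames


def _background_frames(spec: StimulusSpec) -> np.ndarray:
    if spec.background_kind == "uniform":
        value = int(np.clip(np.rint(spec.background_grey), 0, 255))
        return np.full(
            (spec.duration, spec.field_height, spec.field_width), value, dtype=np.uint8
        )
    return render_clutter_background(
        spec.field_width,
        spec.field_height,
        spec.texture_seed,
        spec.background_velocity,
        spec.degrees_per_pixel,
        spec.fps,
        spec.duration,
    )


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------

def render_translation(spec: StimulusSpec) -> Stimulus:
    """A bar or square translating at constant angular velocity.

    The target's top-left corner follows the analytic trajectory
    ``corner0 + px_per_frame * t`` along the stated axis, rounded to the
    nearest pixel per frame; target pixels replace background pixels.  By
    default the target starts flush against the edge it moves away from
    (fully inside the field) and is centred on the orthogonal axis.
    """
    if spec.target_kind not in ("bar", "square"):
        raise ValueError("render_translation requires a bar or square target")
    if spec.velocity_axis not in ("horizontal", "vertical"):
        raise ValueError("render_translation requires a horizontal or vertical axis")
    w, h = spec.target_size
    C, R = spec.field_width, spec.field_height
    if w > C or h > R:
        raise ValueError(f"target {w}x{h} does not fit the {C}x{R} field")

    v = spec.px_per_frame
    if spec.target_start is not None:
        x0, y0 = spec.target_start
    elif spec.velocity_axis == "horizontal":
        x0 = 0.0 if v >= 0 else float(C - w)
        y0 = (R - h) / 2.0
    else:
        x0 = (C - w) / 2.0
        y0 = 0.0 if v >= 0 else float(R - h)

    frames = _background_frames(spec).copy()
    grey = int(np.clip(np.rint(spec.target_grey), 0, 255))
    centres = np.empty((spec.duration, 2))
    inside = np.empty(spec.duration, dtype=bool)
    for t in range(spec.duration):
        x, y = (x0 + v * t, y0) if spec.velocity_axis == "horizontal" else (x0, y0 + v * t)
        xi, yi = _round_px(x), _round_px(y)
        xa, xb = max(xi, 0), min(xi + w, C)
        ya, yb = max(yi, 0), min(yi + h, R)
        if xa < xb and ya < yb:
            frames[t, ya:yb, xa:xb] = grey
        centres[t] = (x + (w - 1) / 2.0, y + (h - 1) / 2.0)
        inside[t] = xi >= 0 and yi >= 0 and xi + w <= C and yi + h <= R
    return Stimulus(frames=frames, spec=spec, target_centres=centres, inside=inside)


def render_depth(spec: StimulusSpec) -> Stimulus:
    """A centred disc approaching (growing) or receding (shrinking).

    The disc radius changes linearly by ``px_per_frame`` px per frame from
    ``target_size[0] / 2``; it is clamped (with a log warning) so it never
    exceeds half the smaller field dimension.  A centred disc on a uniform
    background is exactly mirror-symmetric left-right and up-down.
    """
    if spec.target_kind != "disc" or spec.velocity_axis != "depth":
        raise ValueError("render_depth requires a disc target on the depth axis")
    C, R = spec.field_width, spec.field_height
    r0 = spec.target_size[0] / 2.0
    rate = spec.px_per_frame
    r_max = min(C, R) / 2.0
    cx, cy = (C - 1) / 2.0, (R - 1) / 2.0
    yy, xx = np.mgrid[0:R, 0:C]
    dist2 = (xx - cx) ** 2 + (yy - cy) ** 2

    frames = _background_frames(spec).copy()
    grey = int(np.clip(np.rint(spec.target_grey), 0, 255))
    centres = np.full((spec.duration, 2), (cx, cy))
    inside = np.empty(spec.duration, dtype=bool)
    clamped = False
    for t in range(spec.duration):
        r = r0 + rate * t
        if r > r_max:
            r, clamped = r_max, True
        r = max(r, 0.0)
        frames[t, dist2 <= r * r] = grey
        inside[t] = r < r_max
    if clamped:
        log.warning("disc radius clamped to half field (%.1f px)", r_max)
    return Stimulus(frames=frames, spec=spec, target_centres=centres, inside=inside)


def render(spec: StimulusSpec) -> Stimulus:
    """Render any spec: dispatches on target kind and axis."""
    if spec.target_kind == "none":
        frames = _background_frames(spec)
        centres = np.full((spec.duration, 2), np.nan)
        return Stimulus(
            frames=frames,
            spec=spec,
            target_centres=centres,
            inside=np.zeros(spec.duration, dtype=bool),
        )
    if spec.velocity_axis == "depth":
        return render_depth(spec)
    return render_translation(spec)
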