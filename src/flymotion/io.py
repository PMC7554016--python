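"""Frame-sequence and result I/O.

Frame sequences are stored as directories of numbered 8-bit greyscale PNGs
(``frame_00000.png`` ...).  ``read_frames`` also accepts a single multi-frame
file (e.g. an animated PNG/GIF or video) through imageio, converting to
greyscale if needed.  Run outputs are a per-frame response CSV plus a JSON
manifest recording every parameter actually used.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "write_png_sequence",
    "read_png_sequence",
    "read_frames",
    "write_manifest",
    "dump_layer_grid",
]


def write_png_sequence(directory, frames: np.ndarray) -> list[Path]:
    """Write (T, R, C) uint8 frames as numbered greyscale PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    paths = []
    for t, frame in enumerate(frames):
        p = directory / f"frame_{t:05d}.png"
        iio.imwrite(p, frame.astype(np.uint8))
        paths.append(p)
    return paths


def _to_grey(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:  # RGB(A) -> luminance
        img = img[..., :3].mean(axis=-1)
    return img.astype(np.uint8)


def read_png_sequence(directory) -> np.ndarray:
    directory = Path(directory)
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG frames found in {directory}")
    return np.stack([_to_grey(iio.imread(p)) for p in paths])


def read_frames(path) -> np.ndarray:
    """Read a frame sequence from a PNG directory or a multi-frame file."""
    path = Path(path)
    if path.is_dir():
        return read_png_sequence(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    imgs = iio.imread(path, index=None)
    imgs = np.asarray(imgs)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.ndim == 4 or (imgs.ndim == 3 and imgs.shape[-1] in (3, 4)):
        imgs = np.stack([_to_grey(im) for im in imgs]) if imgs.ndim == 4 else _to_grey(imgs)[None]
    if imgs.shape[0] == 0:
        raise ValueError(f"{path} contains no frames")
    return imgs.astype(np.uint8)


def write_manifest(path, **entries) -> None:
    """JSON manifest of a run (parameters, stimulus spec, seed, versions)."""
    from . import __version__

    payload = {"flymotion_version": __version__, **entries}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def dump_layer_grid(path, name: str, array: np.ndarray) -> None:
    """Raw text grid of one layer map, for inspection/debugging."""
    header = f"{name} shape={array.shape}"
    np.savetxt(path, np.asarray(array, dtype=float), fmt="%.6g", header=header)
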