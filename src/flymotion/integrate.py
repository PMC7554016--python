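"""Lobula-plate layer: wide-field pooling, opponency, and the sigmoid readout.

The tangential-cell stage sums each direction's T4+T5 maps over the whole
field (LP_r, LP_l, LP_d, LP_u).  Sign-inverting opponency between opposite
sub-layers gives the horizontal and vertical systems

    HS_raw = LP_r - LP_l,   VS_raw = LP_d - LP_u,

so rightward / downward motion (the preferred directions) drives positive
output and leftward / upward drives negative output.  Each raw sum is passed
through an odd, saturating sigmoid scaled by the field size, bounding the
activated HS/VS in (-1, 1).

``run_model`` streams a frame sequence through the whole pipeline
(retina -> lamina -> DS layer -> lobula plate) and returns a
``SystemResponse`` time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correlator, prefilter
from .params import ModelParams

__all__ = [
    "SystemResponse",
    "pool_lptc",
    "opponency",
    "activate",
    "run_model",
    "VisualSystem",
]


def pool_lptc(
    T4: dict[str, np.ndarray], T5: dict[str, np.ndarray]
) -> tuple[float, float, float, float]:
    """Wide-field sums LP_dir = sum_xy (T4_dir + T5_dir), one scalar each."""
    return tuple(float(np.sum(T4[d]) + np.sum(T5[d])) for d in ("r", "l", "d", "u"))


def opponency(lp: tuple[float, float, float, float]) -> tuple[float, float]:
    """Sign-inverting opponency: HS_raw = LP_r - LP_l, VS_raw = LP_d - LP_u."""
    lp_r, lp_l, lp_d, lp_u = lp
    return lp_r - lp_l, lp_d - lp_u

def activate(x, C: int, R: int, k: float):
    """Odd sigmoid f(x) = 2*sgn(x)*((1 + exp(-|x|/(C*R*k)))^-1 - 1/2).

    Strictly increasing, f(0) = 0, and |f| < 1 for any finite input; the
    field size C*R times the scale coefficient k normalises the wide-field
    sum so fields of different sizes activate comparably.
    """
    scale = C * R * k
    if scale <= 0:
        raise ValueError("C * R * k must be positive")
    x = np.asarray(x, dtype=float)
    out = 2.0 * np.sign(x) * (1.0 / (1.0 + np.exp(-np.abs(x) / scale)) - 0.5)
    return float(out) if out.ndim == 0 else out


@dataclass
class SystemResponse:
    """Per-frame wide-field responses of the model.

    All fields are 1-D arrays of length T (number of frames).  ``HS`` and
    ``VS`` are the activated outputs in (-1, 1); positive means preferred
    direction (rightward / downward), negative null direction.
    """

    LP_r: np.ndarray
    LP_l: np.ndarray
    LP_d: np.ndarray
    LP_u: np.ndarray
    HS_raw: np.ndarray
    VS_raw: np.ndarray
    HS: np.ndarray
    VS: np.ndarray
    fps: float = 30.0

    def __len__(self) -> int:
        return len(self.HS)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self)) * 1000.0 / self.fps

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "time_ms": self.time_ms,
                "LP_r": self.LP_r,
                "LP_l": self.LP_l,
                "LP_d": self.LP_d,
                "LP_u": self.LP_u,
                "HS_raw": self.HS_raw,
                "VS_raw": self.VS_raw,
                "HS": self.HS,
                "VS": self.VS,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_model(
    frames: np.ndarray,
    params: ModelParams | None = None,
    layer_hook=None,
) -> SystemResponse:
    """Stream a frame sequence through the full pipeline.

    Parameters
    ----------
    frames : array (T, R, C)
        Grey-scale luminance sequence on the 0-255 scale (any dtype).
    params : ModelParams, optional
        Model parameters; defaults to the standard operating point.
    layer_hook : callable, optional
        Called as ``layer_hook(t, layers)`` once per frame with a dict of
        the intermediate maps (P, LA, L1, L2, M1, M2, T4, T5) for debugging
        or layer dumps.

    Returns
    -------
    SystemResponse
        Per-frame wide-field sums and activated HS/VS outputs.  With the
        default initialisation the first frame's outputs are exactly zero.
    """
    params = params or ModelParams()
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected frames of shape (T, R, C), got {frames.shape}")
    n_frames, n_rows, n_cols = frames.shape
    if n_frames == 0:
        raise ValueError("empty frame sequence")

    retina = prefilter.RetinaState.from_first_frame(frames[0], params)
    adapt: prefilter.AdaptState | None = None
    ds_state = correlator.DSState()

    cols = {name: np.empty(n_frames) for name in
            ("LP_r", "LP_l", "LP_d", "LP_u", "HS_raw", "VS_raw", "HS", "VS")}

    for t in range(n_frames):
        try:
            p = prefilter.retina_step(frames[t], retina, params)
            la = prefilter.vdog(p, params) if params.enable_vdog else p
            l1, l2 = prefilter.rectify(la)
            if params.enable_fdsr:
                if adapt is None:
                    adapt = prefilter.AdaptState.from_first_maps(l1, l2)
                m1, m2 = prefilter.fdsr_step(l1, l2, adapt, params)
            else:
                m1, m2 = l1, l2
            ds = correlator.ds_step(m1, m2, ds_state, params)
            lp = pool_lptc(ds.T4, ds.T5)
            hs_raw, vs_raw = opponency(lp)
        except Exception as exc:  # add frame context to layer errors
            raise RuntimeError(f"model failure at frame {t}: {exc}") from exc
        cols["LP_r"][t], cols["LP_l"][t], cols["LP_d"][t], cols["LP_u"][t] = lp
        cols["HS_raw"][t] = hs_raw
        cols["VS_raw"][t] = vs_raw
        cols["HS"][t] = activate(hs_raw, n_cols, n_rows, params.k)
        cols["VS"][t] = activate(vs_raw, n_cols, n_rows, params.k)
        if layer_hook is not None:
            layer_hook(t, {"P": p, "LA": la, "L1": l1, "L2": l2,
                           "M1": m1, "M2": m2, "T4": ds.T4, "T5": ds.T5})

    return SystemResponse(fps=params.fps, **cols)


class VisualSystem:
    """Convenience wrapper bundling parameters with the streaming pipeline."""

    def __init__(self, params: ModelParams | None = None):
        self.params = params or ModelParams()

    def run(self, frames: np.ndarray, layer_hook=None) -> SystemResponse:
        return run_model(frames, self.params, layer_hook=layer_hook)
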