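"""Retina and lamina computations: motion pre-filtering of the ON/OFF pathways.

The retina layer turns the luminance stream into a per-pixel brightness-change
signal P with a short exponential persistence.  The lamina layer applies the
vDoG — a centre-surround difference-of-Gaussians with a polarity rule that
keeps only unambiguous ON or OFF contrast — then half-wave rectifies the
result into parallel ON (L1) and OFF (L2) channels, and finally subtracts a
fast-depolarising / slow-repolarising (FDSR) adaptation trace, yielding the
medulla inputs M1 and M2.  Together these two stages suppress slowly varying,
low-spatial-frequency background structure while passing sharp moving edges.

All maps are float64 of shape (R, C) with row 0 at the top; convolutions use
zero padding at the borders.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .params import ModelParams

__all__ = [
    "RetinaState",
    "AdaptState",
    "decay_coefficients",
    "retina_step",
    "gaussian_kernel_1d",
    "vdog",
    "rectify",
    "fdsr_step",
]


def decay_coefficients(n_p: int) -> np.ndarray:
    """Persistence decay coefficients a_i = 1 / (1 + e^i), i = 1..n_p."""
    i = np.arange(1, n_p + 1, dtype=float)
    return 1.0 / (1.0 + np.exp(i))


@dataclass
class RetinaState:
    """Rolling state of the photoreceptor layer.

    ``prev_frame`` holds L(t-1); ``history`` the last ``n_p`` change maps
    P(t-1), P(t-2), ... (most recent first).  Initialising ``prev_frame``
    with the first frame and the history with zeros makes the model output
    exactly zero on the first frame: no spurious onset transient.
    """

    prev_frame: np.ndarray
    history: deque = field(default_factory=deque)
    n_p: int = 2

    @classmethod
    def from_first_frame(cls, frame: np.ndarray, params: ModelParams) -> "RetinaState":
        f = np.asarray(frame, dtype=float)
        return cls(prev_frame=f, history=deque(maxlen=params.n_p or None), n_p=params.n_p)


def retina_step(frame: np.ndarray, state: RetinaState, params: ModelParams) -> np.ndarray:
    """One photoreceptor update: P(t) = L(t) - L(t-1) + sum_i a_i P(t-i)."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != state.prev_frame.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match state {state.prev_frame.shape}"
        )
    p = frame - state.prev_frame
    if params.n_p > 0 and state.history:
        a = decay_coefficients(params.n_p)
        for ai, past in zip(a, state.history):
            p = p + ai * past
    state.prev_frame = frame
    if params.n_p > 0:
        state.history.appendleft(p)
    return p


def gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    """Truncated, unnormalised 1-D Gaussian exp(-u^2/2s^2) / (sqrt(2*pi)*s).

    The outer product of this kernel with itself is the 2-D kernel
    G_sigma(u, v) = exp(-(u^2+v^2)/2s^2) / (2*pi*s^2), which makes the 2-D
    convolution separable.  The kernel is deliberately *not* renormalised to
    unit sum after truncation; the centre-surround subtraction absorbs the
    resulting DC mismatch.
    """
    u = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-(u**2) / (2.0 * sigma**2)) / (np.sqrt(2.0 * np.pi) * sigma)


def _separable_convolve(x: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    y = convolve1d(x, k1d, axis=0, mode="constant", cval=0.0)
    return convolve1d(y, k1d, axis=1, mode="constant", cval=0.0)


def vdog(P: np.ndarray, params: ModelParams) -> np.ndarray:
    """Centre-surround antagonism with ON/OFF polarity selectivity.

    The excitatory map Pe convolves P with a Gaussian of std ``sigma_e``
    truncated at +-round(sigma_e) px, the inhibitory map Pi with a Gaussian
    of std ``sigma_i`` truncated at +-round(sigma_i) px (the surround kernel
    has twice the radius of the centre).  The output is

        LA =  |Pe - Pi|  where Pe >= 0 and Pi >= 0,
        LA = -|Pe - Pi|  where Pe <  0 and Pi <  0,
        LA =  0          where their signs differ.

    The mixed-sign case carries no reliable ON/OFF label and is zeroed.
    """
    P = np.asarray(P, dtype=float)
    ke = gaussian_kernel_1d(params.sigma_e, int(round(params.sigma_e)))
    ki = gaussian_kernel_1d(params.sigma_i, int(round(params.sigma_i)))
    pe = _separable_convolve(P, ke)
    pi = _separable_convolve(P, ki)
    diff = np.abs(pe - pi)
    la = np.where(
        (pe >= 0) & (pi >= 0),
        diff,
        np.where((pe < 0) & (pi < 0), -diff, 0.0),
    )
    return la


def rectify(LA: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectification into the ON (L1) and OFF (L2) channels.

    L1 = [LA]+ keeps luminance increments; L2 = -[LA]- keeps decrements with
    the sign inverted, so both channels are non-negative and mutually
    exclusive per pixel.
    """
    LA = np.asarray(LA, dtype=float)
    return np.maximum(LA, 0.0), -np.minimum(LA, 0.0)


@dataclass
class AdaptState:
    """FDSR adaptation state for the two channels.

    Holds the previous rectified maps (the literal 2-tap form mixes with the
    previous raw sample) and the previous traces (used by the recursive
    variant).  Initialised from the first rectified maps so that M = 0 on
    the first frame.
    """

    prev_L1: np.ndarray
    prev_L2: np.ndarray
    trace_L1: np.ndarray
    trace_L2: np.ndarray

    @classmethod
    def from_first_maps(cls, L1: np.ndarray, L2: np.ndarray) -> "AdaptState":
        L1 = np.asarray(L1, dtype=float)
        L2 = np.asarray(L2, dtype=float)
        return cls(prev_L1=L1, prev_L2=L2, trace_L1=L1.copy(), trace_L2=L2.copy())


def _fdsr_channel(
    L: np.ndarray,
    prev_L: np.ndarray,
    prev_trace: np.ndarray,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    delta = L - prev_L
    alpha = np.where(delta >= 0, params.alpha_1, params.alpha_2)
    mix = prev_trace if params.fdsr_recursive else prev_L
    trace = alpha * L + (1.0 - alpha) * mix
    return L - trace, trace


def fdsr_step(
    L1: np.ndarray, L2: np.ndarray, state: AdaptState, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """One FDSR update per channel: M = L - L_hat.

    The smoothing coefficient is chosen per pixel from the sign of the
    inter-frame change: alpha_1 (fast, tracks rises almost instantly) for
    non-negative change, alpha_2 (slow) for negative change.  Subtracting the
    trace from the signal leaves a temporal high-pass that suppresses any
    sustained component.
    """
    L1 = np.asarray(L1, dtype=float)
    L2 = np.asarray(L2, dtype=float)
    m1, t1 = _fdsr_channel(L1, state.prev_L1, state.trace_L1, params)
    m2, t2 = _fdsr_channel(L2, state.prev_L2, state.trace_L2, params)
    state.prev_L1, state.prev_L2 = L1, L2
    state.trace_L1, state.trace_L2 = t1, t2
    return m1, m2
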