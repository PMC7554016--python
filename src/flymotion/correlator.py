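"""Direction-selective layer: ensembles of same-polarity delay-and-correlate
detectors producing T4 (ON) and T5 (OFF) maps for the four cardinal directions.

Each pixel correlates its own delayed signal with the current signal of
``n_c`` neighbours at distances {sd, 2*sd, ..., n_c*sd} along +x (rightward),
-x (leftward is the transposed pairing), +y (downward) and -y.  The delay is
dynamic: the nearest pair carries the largest latency ``tau_s_max`` and the
farthest the smallest ``tau_s_min``, decreasing linearly with distance, so
that near pairs are tuned to slow and far pairs to fast image motion.

The medulla inputs M1/M2 are half-wave rectified here before delay and
correlation: the signed adaptation output carries decay transients of the
opposite sign, and the correlator ensembles operate on non-negative
interneuron activity only.  All T4/T5 maps are therefore non-negative.

Index convention: maps are (R, C) arrays with row 0 at the top; rightward is
increasing column index, downward is increasing row index.  Correlation
partners falling outside the field contribute zero (no wrap-around).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "DSState",
    "DSMaps",
    "sampling_distances",
    "dynamic_delay_tau",
    "delay_alpha",
    "ds_step",
]

_DIRECTIONS = ("r", "l", "d", "u")


def sampling_distances(params: ModelParams) -> np.ndarray:
    """The correlator lattice {sd, 2*sd, ..., n_c*sd} in px."""
    return params.sd * np.arange(1, params.n_c + 1)


def dynamic_delay_tau(i: int, params: ModelParams) -> float:
    """Distance-dependent delay tau_s(i) in ms, linear and strictly decreasing.

    tau_s(sd) = tau_s_max, tau_s(n_c*sd) = tau_s_min.  With a single
    correlator (n_c = 1) the lone nearest pair carries tau_s_max.
    """
    lattice = sampling_distances(params)
    if i not in lattice:
        raise ValueError(f"distance {i} is not on the lattice {list(lattice)}")
    if params.n_c == 1:
        return params.tau_s_max
    lo, hi = params.sd, params.sd * params.n_c
    frac = (i - lo) / (hi - lo)
    return params.tau_s_max - (params.tau_s_max - params.tau_s_min) * frac


def delay_alpha(tau_s: float, params: ModelParams) -> float:
    """Low-pass mixing coefficient alpha_3 = tau_i / (tau_i + tau_s)."""
    return params.tau_i / (params.tau_i + tau_s)


@dataclass
class DSMaps:
    """Per-pixel direction-selective responses for one frame."""

    T4: dict[str, np.ndarray]
    T5: dict[str, np.ndarray]


@dataclass
class DSState:
    """Rolling state of the DS layer: previous rectified inputs and, for the
    recursive delay variant, one delayed trace per sampling distance."""

    prev_m1: np.ndarray | None = None
    prev_m2: np.ndarray | None = None
    traces_m1: dict[int, np.ndarray] = field(default_factory=dict)
    traces_m2: dict[int, np.ndarray] = field(default_factory=dict)


def _shift(a: np.ndarray, i: int, axis: int) -> np.ndarray:
    """result[..., j, ...] = a[..., j + i, ...] along `axis`, zero beyond."""
    out = np.zeros_like(a)
    if axis == 1:
        out[:, :-i] = a[:, i:]
    else:
        out[:-i, :] = a[i:, :]
    return out


def _channel_maps(
    m: np.ndarray,
    prev_m: np.ndarray,
    traces: dict[int, np.ndarray],
    params: ModelParams,
) -> dict[str, np.ndarray]:
    maps = {d: np.zeros_like(m) for d in _DIRECTIONS}
    for i in sampling_distances(params):
        i = int(i)
        a3 = delay_alpha(dynamic_delay_tau(i, params), params)
        mix = traces.get(i, prev_m) if params.delay_recursive else prev_m
        hat = a3 * m + (1.0 - a3) * mix
        if params.delay_recursive:
            traces[i] = hat
        maps["r"] += hat * _shift(m, i, axis=1)
        maps["l"] += _shift(hat, i, axis=1) * m
        maps["d"] += hat * _shift(m, i, axis=0)
        maps["u"] += _shift(hat, i, axis=0) * m
    return maps


def ds_step(
    M1: np.ndarray, M2: np.ndarray, state: DSState, params: ModelParams
) -> DSMaps:
    """One DS-layer update on the medulla maps of a single frame.

    T4_r(x, y) = sum_i M1_hat(x, y) * M1(x+i, y) and so on for the other
    directions and the OFF channel, where M1_hat is the per-distance delayed
    copy M1_hat(t) = a3 * M1(t) + (1 - a3) * M1(t-1).
    """
    m1 = np.maximum(np.asarray(M1, dtype=float), 0.0)
    m2 = np.maximum(np.asarray(M2, dtype=float), 0.0)
    if state.prev_m1 is None:
        state.prev_m1, state.prev_m2 = m1, m2
    t4 = _channel_maps(m1, state.prev_m1, state.traces_m1, params)
    t5 = _channel_maps(m2, state.prev_m2, state.traces_m2, params)
    state.prev_m1, state.prev_m2 = m1, m2
    return DSMaps(T4=t4, T5=t5)
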