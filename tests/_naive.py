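"""Naive per-pixel reference implementations of every layer.

These deliberately use explicit Python loops and share no code with the
package's vectorised pipeline; they serve as the independent oracle the
fast implementation is checked against on small random inputs.
"""

from __future__ import annotations

import math

import numpy as np


def naive_retina(frames, params):
    """P(t) = L(t) - L(t-1) + sum_i a_i P(t-i), history zero, L(-1) = L(0)."""
    frames = np.asarray(frames, dtype=float)
    T, R, C = frames.shape
    a = [1.0 / (1.0 + math.exp(i)) for i in range(1, params.n_p + 1)]
    P = np.zeros((T, R, C))
    for t in range(T):
        prev = frames[t - 1] if t > 0 else frames[0]
        for y in range(R):
            for x in range(C):
                acc = frames[t, y, x] - prev[y, x]
                for i in range(1, params.n_p + 1):
                    if t - i >= 0:
                        acc += a[i - 1] * P[t - i, y, x]
                P[t, y, x] = acc
    return P


def naive_vdog(P, params):
    P = np.asarray(P, dtype=float)
    R, C = P.shape
    re, ri = int(round(params.sigma_e)), int(round(params.sigma_i))

    def g(u, v, s):
        return math.exp(-(u * u + v * v) / (2 * s * s)) / (2 * math.pi * s * s)

    la = np.zeros((R, C))
    for y in range(R):
        for x in range(C):
            pe = sum(
                P[y - v, x - u] * g(u, v, params.sigma_e)
                for u in range(-re, re + 1)
                for v in range(-re, re + 1)
                if 0 <= y - v < R and 0 <= x - u < C
            )
            pi = sum(
                P[y - v, x - u] * g(u, v, params.sigma_i)
                for u in range(-ri, ri + 1)
                for v in range(-ri, ri + 1)
                if 0 <= y - v < R and 0 <= x - u < C
            )
            if pe >= 0 and pi >= 0:
                la[y, x] = abs(pe - pi)
            elif pe < 0 and pi < 0:
                la[y, x] = -abs(pe - pi)
    return la


def naive_rectify(LA):
    LA = np.asarray(LA, dtype=float)
    return np.maximum(LA, 0.0), np.where(LA < 0, -LA, 0.0)


def naive_fdsr_series(L_seq, params):
    """FDSR over a full series of one channel's rectified maps."""
    L_seq = np.asarray(L_seq, dtype=float)
    T, R, C = L_seq.shape
    M = np.zeros((T, R, C))
    prev = L_seq[0].copy()
    trace = L_seq[0].copy()
    for t in range(T):
        new_trace = np.zeros((R, C))
        for y in range(R):
            for x in range(C):
                delta = L_seq[t, y, x] - prev[y, x]
                alpha = params.alpha_1 if delta >= 0 else params.alpha_2
                mix = trace[y, x] if params.fdsr_recursive else prev[y, x]
                new_trace[y, x] = alpha * L_seq[t, y, x] + (1 - alpha) * mix
                M[t, y, x] = L_seq[t, y, x] - new_trace[y, x]
        prev = L_seq[t].copy()
        trace = new_trace
    return M


def naive_tau_s(i, params):
    if params.n_c == 1:
        return params.tau_s_max
    lo, hi = params.sd, params.sd * params.n_c
    return params.tau_s_max - (params.tau_s_max - params.tau_s_min) * (i - lo) / (hi - lo)


def naive_ds_series(M_seq, params):
    """Direction-selective maps over a full series of one channel."""
    M_seq = np.asarray(M_seq, dtype=float)
    T, R, C = M_seq.shape
    dists = [params.sd * j for j in range(1, params.n_c + 1)]
    m = np.maximum(M_seq, 0.0)
    out = {d: np.zeros((T, R, C)) for d in "rldu"}
    traces = {}
    prev = m[0].copy()
    for t in range(T):
        new_traces = {}
        for i in dists:
            a3 = params.tau_i / (params.tau_i + naive_tau_s(i, params))
            mix = traces.get(i, prev) if params.delay_recursive else prev
            hat = a3 * m[t] + (1 - a3) * mix
            new_traces[i] = hat
            for y in range(R):
                for x in range(C):
                    if x + i < C:
                        out["r"][t, y, x] += hat[y, x] * m[t, y, x + i]
                        out["l"][t, y, x] += hat[y, x + i] * m[t, y, x]
                    if y + i < R:
                        out["d"][t, y, x] += hat[y, x] * m[t, y + i, x]
                        out["u"][t, y, x] += hat[y + i, x] * m[t, y, x]
        prev = m[t].copy()
        traces = new_traces
    return out


def naive_pool(T4, T5):
    sums = []
    for d in "rldu":
        acc = 0.0
        R, C = T4[d].shape
        for y in range(R):
            for x in range(C):
                acc += T4[d][y, x] + T5[d][y, x]
        sums.append(acc)
    return tuple(sums)


def naive_activate(x, C, R, k):
    if x == 0:
        return 0.0
    s = 1.0 if x > 0 else -1.0
    return 2.0 * s * (1.0 / (1.0 + math.exp(-abs(x) / (C * R * k))) - 0.5)


def naive_model(frames, params):
    """Full pipeline via the naive layers; returns HS/VS series and layers."""
    frames = np.asarray(frames, dtype=float)
    T, R, C = frames.shape
    P = naive_retina(frames, params)
    LA = np.stack([naive_vdog(P[t], params) if params.enable_vdog else P[t] for t in range(T)])
    L1 = np.zeros_like(LA)
    L2 = np.zeros_like(LA)
    for t in range(T):
        L1[t], L2[t] = naive_rectify(LA[t])
    if params.enable_fdsr:
        M1 = naive_fdsr_series(L1, params)
        M2 = naive_fdsr_series(L2, params)
    else:
        M1, M2 = L1, L2
    T4 = naive_ds_series(M1, params)
    T5 = naive_ds_series(M2, params)
    hs = np.zeros(T)
    vs = np.zeros(T)
    for t in range(T):
        lp = naive_pool({d: T4[d][t] for d in "rldu"}, {d: T5[d][t] for d in "rldu"})
        hs[t] = naive_activate(lp[0] - lp[1], C, R, params.k)
        vs[t] = naive_activate(lp[2] - lp[3], C, R, params.k)
    return {"P": P, "LA": LA, "L1": L1, "L2": L2, "M1": M1, "M2": M2,
            "T4": T4, "T5": T5, "HS": hs, "VS": vs}
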