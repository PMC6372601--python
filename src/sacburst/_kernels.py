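"""Numba-compiled inner loops for the fixed-step integrators.

Parameters are passed as a flat float64 array in :data:`sacburst.params.PARAM_ORDER`;
the index constants below must stay in sync with that tuple.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the packed parameter array (see params.PARAM_ORDER)
_CM, _GL, _GC, _GK, _GSAHP = 0, 1, 2, 3, 4
_VL, _VC, _VK = 5, 6, 7
_V1, _V2, _V3, _V4 = 8, 9, 10, 11
_TAUN, _TAUR, _TAUS, _TAUC = 12, 13, 14, 15
_DELTAC, _ALPHAS, _ALPHAC, _ALPHAR = 16, 17, 18, 19
_HX, _C0 = 20, 21


@njit(cache=True)
def em_full(y0, p, seg_ends, seg_currs, dt, n_steps, stride, sigma, seed, out):
    """Euler-Maruyama integration of the full 5D system.

    Noise enters only the voltage equation, as ``(sigma/C_m) sqrt(dt) z`` per
    step with ``z`` standard normal, so the injected current has spectral
    density ``sigma**2``. Gating variables are clamped to [0, 1] and calcium
    to >= 0 after each step; the number of clamped steps is returned.

    ``out`` must be preallocated with shape ``(n_steps//stride + 1, 5)``;
    row ``k`` receives the state at step ``k*stride``. Returns
    ``(n_clamps, abort_step)`` where ``abort_step`` is -1 on success, or the
    step index at which a non-finite state was produced.
    """
    np.random.seed(seed)
    V, N, C, S, R = y0[0], y0[1], y0[2], y0[3], y0[4]
    Cm = p[_CM]
    noise_amp = sigma * math.sqrt(dt) / Cm
    n_clamps = 0
    seg_idx = 0
    n_segs = seg_ends.shape[0]
    out[0, 0] = V
    out[0, 1] = N
    out[0, 2] = C
    out[0, 3] = S
    out[0, 4] = R
    for step in range(n_steps):
        t = step * dt
        while seg_idx < n_segs - 1 and t >= seg_ends[seg_idx]:
            seg_idx += 1
        I_ext = seg_currs[seg_idx]

        M_inf = 0.5 * (1.0 + math.tanh((V - p[_V1]) / p[_V2]))
        Lam = math.cosh((V - p[_V3]) / (2.0 * p[_V4]))
        N_inf = 0.5 * (1.0 + math.tanh((V - p[_V3]) / p[_V4]))
        I_C = -p[_GC] * M_inf * (V - p[_VC])
        I_total = (
            -p[_GL] * (V - p[_VL])
            + I_C
            - p[_GK] * N * (V - p[_VK])
            - p[_GSAHP] * R**4 * (V - p[_VK])
            + I_ext
        )
        dV = I_total / Cm
        dN = Lam * (N_inf - N) / p[_TAUN]
        dC = (-(p[_ALPHAC] / p[_HX]) * C + p[_C0] + p[_DELTAC] * I_C) / p[_TAUC]
        dS = (p[_ALPHAS] * C**4 * (1.0 - S) - S) / p[_TAUS]
        dR = (p[_ALPHAR] * S * (1.0 - R) - R) / p[_TAUR]

        V = V + dt * dV
        if sigma > 0.0:
            V += noise_amp * np.random.normal()
        N = N + dt * dN
        C = C + dt * dC
        S = S + dt * dS
        R = R + dt * dR

        clamped = False
        if N < 0.0:
            N = 0.0
            clamped = True
        elif N > 1.0:
            N = 1.0
            clamped = True
        if S < 0.0:
            S = 0.0
            clamped = True
        elif S > 1.0:
            S = 1.0
            clamped = True
        if R < 0.0:
            R = 0.0
            clamped = True
        elif R > 1.0:
            R = 1.0
            clamped = True
        if C < 0.0:
            C = 0.0
            clamped = True
        if clamped:
            n_clamps += 1

        if not (math.isfinite(V) and math.isfinite(C)):
            return n_clamps, step

        k = step + 1
        if k % stride == 0:
            row = k // stride
            out[row, 0] = V
            out[row, 1] = N
            out[row, 2] = C
            out[row, 3] = S
            out[row, 4] = R
    return n_clamps, -1


@njit(cache=True)
def euler_fast(V0, N0, p, I_tot, dt, n_steps, stride, out):
    """Deterministic Euler integration of the planar fast subsystem.

    ``out`` has shape ``(n_steps//stride + 1, 2)``. Returns the abort step
    (-1 on success).
    """
    V, N = V0, N0
    Cm = p[_CM]
    out[0, 0] = V
    out[0, 1] = N
    for step in range(n_steps):
        M_inf = 0.5 * (1.0 + math.tanh((V - p[_V1]) / p[_V2]))
        Lam = math.cosh((V - p[_V3]) / (2.0 * p[_V4]))
        N_inf = 0.5 * (1.0 + math.tanh((V - p[_V3]) / p[_V4]))
        dV = (
            -p[_GL] * (V - p[_VL])
            - p[_GC] * M_inf * (V - p[_VC])
            - p[_GK] * N * (V - p[_VK])
            + I_tot
        ) / Cm
        dN = Lam * (N_inf - N) / p[_TAUN]
        V = V + dt * dV
        N = N + dt * dN
        if not math.isfinite(V):
            return step
        k = step + 1
        if k % stride == 0:
            out[k // stride, 0] = V
            out[k // stride, 1] = N
    return -1


@njit(cache=True)
def burst_bounds(C, threshold, min_samples):
    """Index bounds (start, stop) of above-threshold calcium runs.

    A run is kept if it spans at least ``min_samples`` samples and does not
    touch either trace boundary. ``stop`` is exclusive.
    """
    n = C.shape[0]
    starts = []
    stops = []
    in_run = False
    start = 0
    for i in range(n):
        if C[i] > threshold:
            if not in_run:
                in_run = True
                start = i
        else:
            if in_run:
                in_run = False
                if start > 0 and i - start >= min_samples:
                    starts.append(start)
                    stops.append(i)
    # a run still open at the end touches the right boundary: discarded
    return starts, stops
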