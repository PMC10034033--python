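"""Numba-compiled voxel-wise Nelder-Mead kernel.

Same objective and simplex scheme as the numpy path in :mod:`perfmap.nlr`
(clamped box-IRF SSE, scipy-style initial simplex, standard coefficients,
fixed iteration count), specialized for a uniform AIF time grid.  Importing
this module is optional; :func:`perfmap.nlr.fit_voxels` falls back to the
vectorized numpy implementation when numba is unavailable.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _aif_integral(x, t0, dt, n, tarr, varr, slope, F):
    if x <= tarr[0]:
        return 0.0
    if x >= tarr[n - 1]:
        x = tarr[n - 1]
    i = int((x - t0) / dt)
    if i > n - 2:
        i = n - 2
    if i < 0:
        i = 0
    d = x - tarr[i]
    return F[i] + varr[i] * d + 0.5 * slope[i] * d * d


@njit(cache=True, fastmath=False)
def _sse(p, curve, times, k, lo, hi, energy, t0, dt, n, tarr, varr, slope, F):
    # clamped model SSE plus a quadratic out-of-bounds penalty (energy-
    # scaled), matching perfmap.nlr._clipped_sse_factory exactly
    cbf = min(max(p[0], lo[0]), hi[0])
    mtt = min(max(p[1], lo[1]), hi[1])
    dly = min(max(p[2], lo[2]), hi[2])
    s = 0.0
    for j in range(times.shape[0]):
        u = times[j] - dly
        a = _aif_integral(u, t0, dt, n, tarr, varr, slope, F)
        b = _aif_integral(u - mtt, t0, dt, n, tarr, varr, slope, F)
        e = k * cbf * (a - b) - curve[j]
        s += e * e
    pen = 0.0
    pen += ((p[0] - cbf) / (hi[0] - lo[0])) ** 2
    pen += ((p[1] - mtt) / (hi[1] - lo[1])) ** 2
    pen += ((p[2] - dly) / (hi[2] - lo[2])) ** 2
    return s + energy * pen


@njit(cache=True, fastmath=False)
def fit_all(curves, times, init, lo, hi, n_iter, k,
            t0, dt, n, tarr, varr, slope, F):
    """Nelder-Mead fit of every row of ``curves``; returns (V, 4) params+sse."""
    V = curves.shape[0]
    out = np.empty((V, 4))
    sim = np.empty((4, 3))
    fsim = np.empty(4)
    xbar = np.empty(3)
    xr = np.empty(3)
    xe = np.empty(3)
    xc = np.empty(3)

    for vox in range(V):
        curve = curves[vox]
        energy = 1.0
        for j in range(times.shape[0]):
            energy += curve[j] * curve[j]
        for j in range(3):
            sim[0, j] = init[j]
        for kk in range(3):
            for j in range(3):
                sim[kk + 1, j] = init[j]
            if init[kk] != 0.0:
                sim[kk + 1, kk] = init[kk] * 1.05
            else:
                sim[kk + 1, kk] = 0.00025
        for kk in range(4):
            fsim[kk] = _sse(sim[kk], curve, times, k, lo, hi, energy,
                            t0, dt, n, tarr, varr, slope, F)

        for _ in range(n_iter):
            # insertion sort of the 4 vertices by objective (stable)
            for a in range(1, 4):
                fv = fsim[a]
                x0_, x1_, x2_ = sim[a, 0], sim[a, 1], sim[a, 2]
                b = a - 1
                while b >= 0 and fsim[b] > fv:
                    fsim[b + 1] = fsim[b]
                    sim[b + 1, 0] = sim[b, 0]
                    sim[b + 1, 1] = sim[b, 1]
                    sim[b + 1, 2] = sim[b, 2]
                    b -= 1
                fsim[b + 1] = fv
                sim[b + 1, 0], sim[b + 1, 1], sim[b + 1, 2] = x0_, x1_, x2_

            for j in range(3):
                xbar[j] = (sim[0, j] + sim[1, j] + sim[2, j]) / 3.0
                xr[j] = 2.0 * xbar[j] - sim[3, j]
            fxr = _sse(xr, curve, times, k, lo, hi, energy,
                       t0, dt, n, tarr, varr, slope, F)

            if fxr < fsim[0]:
                for j in range(3):
                    xe[j] = xbar[j] + 2.0 * (xbar[j] - sim[3, j])
                fxe = _sse(xe, curve, times, k, lo, hi, energy,
                           t0, dt, n, tarr, varr, slope, F)
                if fxe < fxr:
                    for j in range(3):
                        sim[3, j] = xe[j]
                    fsim[3] = fxe
                else:
                    for j in range(3):
                        sim[3, j] = xr[j]
                    fsim[3] = fxr
            elif fxr < fsim[2]:
                for j in range(3):
                    sim[3, j] = xr[j]
                fsim[3] = fxr
            else:
                shrink = False
                if fxr < fsim[3]:
                    for j in range(3):
                        xc[j] = xbar[j] + 0.5 * (xbar[j] - sim[3, j])
                    fxc = _sse(xc, curve, times, k, lo, hi, energy,
                               t0, dt, n, tarr, varr, slope, F)
                    if fxc <= fxr:
                        for j in range(3):
                            sim[3, j] = xc[j]
                        fsim[3] = fxc
                    else:
                        shrink = True
                else:
                    for j in range(3):
                        xc[j] = xbar[j] - 0.5 * (xbar[j] - sim[3, j])
                    fxc = _sse(xc, curve, times, k, lo, hi, energy,
                               t0, dt, n, tarr, varr, slope, F)
                    if fxc < fsim[3]:
                        for j in range(3):
                            sim[3, j] = xc[j]
                        fsim[3] = fxc
                    else:
                        shrink = True
                if shrink:
                    for kk in range(1, 4):
                        for j in range(3):
                            sim[kk, j] = sim[0, j] + 0.5 * (sim[kk, j] - sim[0, j])
                        fsim[kk] = _sse(sim[kk], curve, times, k, lo, hi, energy,
                                        t0, dt, n, tarr, varr, slope, F)

        best = 0
        for kk in range(1, 4):
            if fsim[kk] < fsim[best]:
                best = kk
        for j in range(3):
            out[vox, j] = min(max(sim[best, j], lo[j]), hi[j])
        out[vox, 3] = fsim[best]
    return out
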