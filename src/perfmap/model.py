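"""Forward model: bolus curve, box impulse response, tissue curve synthesis.

The tissue model is the convolution of the arterial input with a rectangular
impulse response of height CBF (SI units), width MTT and temporal offset
``delay``::

    c(t) = k * CBF_SI * integral of AIF over [t - delay - MTT, t - delay]

The sampled AIF is treated as piecewise linear and zero outside its grid, so
the integral has a closed form and the curve is smooth in all three
parameters (which the simplex fitter relies on).  ``HU_PER_CONCENTRATION``
is the k that converts tracer concentration to attenuation; synthesis and
fitting share it, so maps round-trip exactly.
"""
from __future__ import annotations

import numpy as np

from .core import AIFCurve

__all__ = [
    "gamma_variate_aif",
    "AIFIntegral",
    "tissue_curve",
    "HU_PER_CONCENTRATION",
    "CBF_SI_SCALE",
]

#: HU produced per unit tracer concentration; assumed 1 (linear attenuation).
HU_PER_CONCENTRATION = 1.0

#: mL/100g/min -> per-second flow in mL/g/s: divide by 100 g and 60 s.
CBF_SI_SCALE = 1.0 / 6000.0


def gamma_variate_aif(aif_params, times) -> AIFCurve:
    """Peak-normalized gamma-variate bolus curve on ``times``.

    ``aif_params`` is a mapping with keys ``t0`` (bolus arrival, s),
    ``alpha`` (shape, unitless), ``beta`` (time scale, s) and ``amplitude``
    (peak height, HU).  The maximum equals ``amplitude`` and is reached at
    ``t0 + alpha * beta``; the curve is identically zero up to ``t0``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    t0 = float(aif_params["t0"])
    alpha = float(aif_params["alpha"])
    beta = float(aif_params["beta"])
    amplitude = float(aif_params["amplitude"])
    if alpha <= 0 or beta <= 0 or amplitude <= 0:
        raise ValueError("alpha, beta and amplitude must be positive")
    dt = t - t0
    values = np.zeros_like(t)
    pos = dt > 0
    x = dt[pos] / (alpha * beta)
    values[pos] = amplitude * x ** alpha * np.exp(alpha * (1.0 - x))
    return AIFCurve(times=t, values=values)


class AIFIntegral:
    """Running integral of a piecewise-linear AIF, vectorized over queries.

    The curve is linearly interpolated between samples and taken as zero
    outside the grid, so the integral is constant beyond the last sample.
    Uniform grids take a fast arithmetic-indexing path.
    """

    def __init__(self, aif: AIFCurve):
        self.t = aif.times
        self.v = aif.values
        seg = np.diff(self.t)
        self._slope = np.diff(self.v) / seg
        # cumulative trapezoid areas, F[i] = integral up to t[i]
        areas = 0.5 * (self.v[:-1] + self.v[1:]) * seg
        self._F = np.concatenate([[0.0], np.cumsum(areas)])
        self._dt = float(seg[0])
        self._uniform = bool(np.allclose(seg, self._dt, rtol=1e-9, atol=1e-12))
        self.total = float(self._F[-1])

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.t[0], self.t[-1])
        if self._uniform:
            idx = np.floor((xc - self.t[0]) / self._dt).astype(np.int64)
            idx = np.clip(idx, 0, self.t.size - 2)
        else:
            idx = np.clip(np.searchsorted(self.t, xc, side="right") - 1,
                          0, self.t.size - 2)
        d = xc - self.t[idx]
        return self._F[idx] + self.v[idx] * d + 0.5 * self._slope[idx] * d * d

    def window(self, upper, width):
        """Integral over ``[upper - width, upper]``; fused two-point query."""
        both = self(np.concatenate([upper, upper - width], axis=-1))
        n = upper.shape[-1]
        return both[..., :n] - both[..., n:]


def tissue_curve(aif, cbf, mtt, delay, times=None):
    """Tissue time-attenuation curve for box-IRF parameters.

    ``aif`` may be an :class:`AIFCurve` or a prebuilt :class:`AIFIntegral`
    (reuse the latter when evaluating many parameter sets).  ``cbf``, ``mtt``
    and ``delay`` broadcast against each other; the returned array has their
    broadcast shape plus a trailing time axis.
    """
    if isinstance(aif, AIFIntegral):
        F = aif
        if times is None:
            raise ValueError("times is required when passing an AIFIntegral")
    else:
        F = AIFIntegral(aif)
        times = aif.times if times is None else times
    t = np.asarray(times, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    mtt = np.asarray(mtt, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if np.any(mtt <= 0):
        raise ValueError("mtt must be positive")
    if np.any(cbf < 0):
        raise ValueError("cbf must be non-negative")
    shape = np.broadcast_shapes(cbf.shape, mtt.shape, delay.shape)
    cbf, mtt, delay = (np.broadcast_to(a, shape)[..., None]
                       for a in (cbf, mtt, delay))
    tt = t.reshape((1,) * len(shape) + (-1,)) if shape else t
    upper = F(tt - delay)
    lower = F(tt - delay - mtt)
    return HU_PER_CONCENTRATION * CBF_SI_SCALE * cbf * (upper - lower)
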