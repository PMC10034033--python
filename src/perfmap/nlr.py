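"""Voxel-wise box-IRF non-linear regression and automatic AIF/VOF selection.

Each voxel's baseline-subtracted attenuation curve is fit with the three
parameters (CBF, MTT, delay) of the box impulse response by downhill-simplex
minimization of the sum of squared errors (300 iterations, initial point
CBF=60 mL/100g/min, MTT=5 s, delay=3.5 s).  CBV follows from the central
volume principle.  ``fit_voxel`` is the scalar reference path (scipy's
Nelder-Mead); ``fit_voxels`` is a vectorized simplex that fits whole volumes
at once and is what ``compute_maps`` uses.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import AIFCurve, CTPStack, ParamMaps, PerfusionParams
from .model import AIFIntegral, CBF_SI_SCALE, HU_PER_CONCENTRATION, tissue_curve

__all__ = [
    "NLRConfig",
    "model_tissue_curve",
    "fit_voxel",
    "fit_voxels",
    "select_aif",
    "select_vof",
    "compute_maps",
    "derive_brain_mask",
]


@dataclass
class NLRConfig:
    init: tuple = (60.0, 5.0, 3.5)            # CBF, MTT, delay
    cbf_bounds: tuple = (0.0, 200.0)
    mtt_bounds: tuple = (0.1, 30.0)
    delay_bounds: tuple = (0.0, 20.0)
    max_iter: int = 300
    arrival_fraction: float = 0.05            # AIF threshold for bolus arrival
    mask_threshold_hu: float = 20.0           # brain-mask fallback on mean HU
    norm_constants: dict | None = None
    engine: str = "auto"                      # "auto" | "numba" | "numpy"
    #: fallback starts for curves the first simplex run leaves unexplained
    #: (late bolus arrival sits outside the capture range of the standard
    #: init); the best of all runs wins
    restart_inits: tuple = ((60.0, 5.0, 12.0), (60.0, 5.0, 18.0))

    @property
    def lower(self):
        return np.array([self.cbf_bounds[0], self.mtt_bounds[0],
                         self.delay_bounds[0]])

    @property
    def upper(self):
        return np.array([self.cbf_bounds[1], self.mtt_bounds[1],
                         self.delay_bounds[1]])


def model_tissue_curve(aif, cbf, mtt, delay, times=None):
    """Box-IRF forward model on the acquisition grid (see :mod:`perfmap.model`)."""
    return tissue_curve(aif, cbf, mtt, delay, times)


def _clipped_sse_factory(curves, F, times, lo, hi):
    """SSE objective over (M, 3) parameter blocks, with bound clamping.

    Out-of-bounds excursions are clamped for the model evaluation and add a
    quadratic penalty scaled by the target-curve energy; without it the
    clipped objective is flat beyond the bounds and the simplex can
    degenerate onto the clamp plateau (e.g. CBF pinned at its upper bound).
    """
    t = np.asarray(times, dtype=float)
    k = HU_PER_CONCENTRATION * CBF_SI_SCALE
    span = hi - lo
    energy = np.einsum("ij,ij->i", curves, curves) + 1.0

    def sse(x, rows=None):
        xc = np.clip(x, lo, hi)
        model = (k * xc[:, 0:1]) * F.window(t - xc[:, 2:3], xc[:, 1:2])
        tgt = curves if rows is None else curves[rows]
        d = model - tgt
        viol = (x - xc) / span
        pen = (energy if rows is None else energy[rows]) \
            * np.einsum("ij,ij->i", viol, viol)
        return np.einsum("ij,ij->i", d, d) + pen

    return sse


def fit_voxel(curve, aif, times=None, init=None, bounds=None,
              config: NLRConfig | None = None) -> PerfusionParams:
    """Fit one baseline-subtracted tissue curve (scalar reference path)."""
    cfg = config or NLRConfig()
    if init is not None:
        cfg = dataclass_replace(cfg, init=tuple(init))
    if bounds is not None:
        cfg = dataclass_replace(cfg, cbf_bounds=tuple(bounds[0]),
                                mtt_bounds=tuple(bounds[1]),
                                delay_bounds=tuple(bounds[2]))
    curve = np.asarray(curve, dtype=float)
    if isinstance(aif, AIFIntegral):
        F = aif
        if times is None:
            raise ValueError("times is required with a prebuilt AIFIntegral")
    else:
        F = AIFIntegral(aif)
        times = aif.times if times is None else np.asarray(times, dtype=float)

    if np.ptp(curve) == 0 and abs(curve[0]) < 1e-12:
        init_ = cfg.init
        return PerfusionParams(cbf=0.0, mtt=init_[1], delay=init_[2],
                               sse=0.0, flag="no-signal")

    lo, hi = cfg.lower, cfg.upper
    obj = _clipped_sse_factory(curve[None, :], F, times, lo, hi)

    def run(start):
        res = minimize(lambda p: float(obj(p[None, :])[0]),
                       np.asarray(start, dtype=float), method="Nelder-Mead",
                       options={"maxiter": cfg.max_iter, "xatol": 1e-8,
                                "fatol": 1e-12})
        xs = np.clip(res.x, lo, hi)
        return xs, float(obj(xs[None, :])[0])

    x, sse = run(cfg.init)
    if cfg.restart_inits:
        energy = float(curve @ curve) + 1.0
        floor = 0.0
        if curve.size >= 4:
            d2 = curve[:-2] - 2 * curve[1:-1] + curve[2:]
            floor = curve.size * float((d2 * d2).mean()) / 6.0
        threshold = max(1e-4 * energy, 4.0 * floor)
        for init2 in cfg.restart_inits:
            if sse <= threshold:
                break
            x2, s2 = run(init2)
            if s2 < sse:
                x, sse = x2, s2
    flag = "truncated" if x[1] + x[2] > times[-1] else "ok"
    return PerfusionParams(cbf=float(x[0]), mtt=float(x[1]), delay=float(x[2]),
                           sse=sse, flag=flag)


def dataclass_replace(cfg, **kw):
    import dataclasses
    return dataclasses.replace(cfg, **kw)


def _batched_nelder_mead(f, x0, n_iter):
    """Fixed-iteration Nelder-Mead run in parallel over rows of ``x0``.

    ``f(x, rows=None)`` evaluates an (M, n) parameter block.  Uses the
    standard coefficients (reflect 1, expand 2, contract 0.5, shrink 0.5)
    and scipy's initial-simplex construction.  Returns (x_best, f_best).
    """
    x0 = np.asarray(x0, dtype=float)
    V, n = x0.shape
    sim = np.repeat(x0[:, None, :], n + 1, axis=1)
    for k in range(n):
        col = sim[:, k + 1, k]
        sim[:, k + 1, k] = np.where(col != 0, col * 1.05, 0.00025)
    fsim = np.stack([f(sim[:, j]) for j in range(n + 1)], axis=1)

    rho, chi, psi, sigma = 1.0, 2.0, 0.5, 0.5
    rows = np.arange(V)
    for _ in range(n_iter):
        order = np.argsort(fsim, axis=1, kind="stable")
        sim = np.take_along_axis(sim, order[:, :, None], axis=1)
        fsim = np.take_along_axis(fsim, order, axis=1)

        xbar = sim[:, :-1].mean(axis=1)
        dworst = xbar - sim[:, -1]
        xr = xbar + rho * dworst
        fxr = f(xr)

        f0, fn1, fn = fsim[:, 0], fsim[:, -2], fsim[:, -1]
        new_x = np.empty_like(xr)
        new_f = np.empty_like(fxr)
        shrink = np.zeros(V, dtype=bool)

        expand_try = fxr < f0
        if np.any(expand_try):
            idx = rows[expand_try]
            xe = xbar[idx] + rho * chi * dworst[idx]
            fxe = f(xe, rows=idx)
            better = fxe < fxr[idx]
            new_x[idx] = np.where(better[:, None], xe, xr[idx])
            new_f[idx] = np.where(better, fxe, fxr[idx])

        accept_r = (~expand_try) & (fxr < fn1)
        new_x[accept_r] = xr[accept_r]
        new_f[accept_r] = fxr[accept_r]

        contract = (~expand_try) & (~accept_r)
        if np.any(contract):
            outside = contract & (fxr < fn)
            if np.any(outside):
                idx = rows[outside]
                xc = xbar[idx] + psi * rho * dworst[idx]
                fxc = f(xc, rows=idx)
                ok = fxc <= fxr[idx]
                new_x[idx] = xc
                new_f[idx] = fxc
                shrink[idx[~ok]] = True
            inside = contract & ~outside
            if np.any(inside):
                idx = rows[inside]
                xcc = xbar[idx] - psi * dworst[idx]
                fxcc = f(xcc, rows=idx)
                ok = fxcc < fn[idx]
                new_x[idx] = xcc
                new_f[idx] = fxcc
                shrink[idx[~ok]] = True

        keep = ~shrink
        sim[keep, -1] = new_x[keep]
        fsim[keep, -1] = new_f[keep]
        if np.any(shrink):
            idx = rows[shrink]
            sim[idx, 1:] = sim[idx, :1] + sigma * (sim[idx, 1:] - sim[idx, :1])
            for j in range(1, n + 1):
                fsim[idx, j] = f(sim[idx, j], rows=idx)

    best = np.argmin(fsim, axis=1)
    return (np.take_along_axis(sim, best[:, None, None], axis=1)[:, 0],
            np.take_along_axis(fsim, best[:, None], axis=1)[:, 0])


def fit_voxels(curves, aif, times=None, config: NLRConfig | None = None):
    """Vectorized fit of many baseline-subtracted curves.

    Returns a dict of arrays ``cbf, mtt, delay, cbv, sse`` plus a ``flag``
    array of strings, all of length ``curves.shape[0]``.
    """
    cfg = config or NLRConfig()
    curves = np.asarray(curves, dtype=float)
    if isinstance(aif, AIFIntegral):
        F = aif
        if times is None:
            raise ValueError("times is required with a prebuilt AIFIntegral")
    else:
        F = AIFIntegral(aif)
        times = aif.times if times is None else np.asarray(times, dtype=float)

    V = curves.shape[0]
    lo, hi = cfg.lower, cfg.upper
    times = np.asarray(times, dtype=float)

    engine = cfg.engine
    if engine == "auto":
        try:
            from . import _fastfit  # noqa: F401
            engine = "numba" if F._uniform else "numpy"
        except ImportError:
            engine = "numpy"
    obj = _clipped_sse_factory(curves, F, times, lo, hi)

    def run(subset, init):
        sub = curves if subset is None else curves[subset]
        init = np.asarray(init, dtype=float)
        if engine == "numba":
            from . import _fastfit
            k = HU_PER_CONCENTRATION * CBF_SI_SCALE
            out = _fastfit.fit_all(
                np.ascontiguousarray(sub, dtype=float), times, init,
                lo, hi, cfg.max_iter, k,
                float(F.t[0]), F._dt, F.t.size, F.t, F.v, F._slope, F._F)
            return np.clip(out[:, :3], lo, hi)
        o = obj if subset is None else _clipped_sse_factory(sub, F, times,
                                                            lo, hi)
        xs, _ = _batched_nelder_mead(o, np.tile(init, (len(sub), 1)),
                                     cfg.max_iter)
        return np.clip(xs, lo, hi)

    x = run(None, cfg.init)
    sse = obj(x)  # pure model SSE at the clipped optimum (no penalty term)

    if cfg.restart_inits:
        # late-arrival curves can sit outside the standard init's capture
        # range; restart where the fit explains much less than the curve's
        # own noise floor (second-difference estimate) allows
        energy = np.einsum("ij,ij->i", curves, curves) + 1.0
        if curves.shape[1] >= 4:
            d2 = curves[:, :-2] - 2 * curves[:, 1:-1] + curves[:, 2:]
            floor = curves.shape[1] * (d2 * d2).mean(axis=1) / 6.0
        else:
            floor = np.zeros(V)
        threshold = np.maximum(1e-4 * energy, 4.0 * floor)
        for init2 in cfg.restart_inits:
            poor = np.nonzero(sse > threshold)[0]
            if not len(poor):
                break
            x2 = run(poor, init2)
            s2 = obj(x2, rows=poor)
            better = s2 < sse[poor]
            x[poor[better]] = x2[better]
            sse[poor[better]] = s2[better]

    no_signal = (np.ptp(curves, axis=1) == 0) & (np.abs(curves[:, 0]) < 1e-12)
    x[no_signal] = [0.0, cfg.init[1], cfg.init[2]]
    sse[no_signal] = 0.0

    flag = np.full(V, "ok", dtype=object)
    flag[x[:, 1] + x[:, 2] > times[-1]] = "truncated"
    flag[no_signal] = "no-signal"
    return {
        "cbf": x[:, 0], "mtt": x[:, 1], "delay": x[:, 2],
        "cbv": x[:, 0] * x[:, 1] / 60.0, "sse": sse, "flag": flag,
    }


def derive_brain_mask(stack: CTPStack, threshold_hu: float = 20.0) -> np.ndarray:
    """Crude brain mask: voxels whose temporal-mean HU exceeds a threshold."""
    return stack.data.mean(axis=3) > threshold_hu


def _arrival_index(values, fraction):
    """First sample index at which a bolus curve exceeds ``fraction`` of peak."""
    values = np.asarray(values, dtype=float)
    peak = values.max()
    if peak <= 0:
        return 1
    above = np.nonzero(values > fraction * peak)[0]
    return int(above[0]) if above.size else 1


def _baseline_subtracted(stack: CTPStack, n_baseline: int):
    n_baseline = max(1, int(n_baseline))
    baseline = stack.data[..., :n_baseline].mean(axis=3, keepdims=True)
    return stack.data - baseline


def _rank_curves(stack: CTPStack, n_voxels, late: bool):
    mask = stack.brain_mask
    if mask is None:
        mask = derive_brain_mask(stack)
    if not mask.any():
        raise ValueError("no candidate voxels: empty brain mask")
    # provisional arrival from the mean in-mask curve
    mean_curve = stack.data[mask].mean(axis=0)
    k = _arrival_index(mean_curve - mean_curve[0], 0.1)
    curves = _baseline_subtracted(stack, k)[mask]
    peaks = curves.max(axis=1)
    t_peak = stack.times[np.argmax(curves, axis=1)]
    t_span = stack.times[-1] - stack.times[0]
    t_hat = (t_peak - stack.times[0]) / t_span
    score = peaks / max(peaks.max(), 1e-12) + (0.5 * t_hat if late else -0.5 * t_hat)
    if len(score) < n_voxels:
        warnings.warn(f"only {len(score)} candidate voxels available "
                      f"(requested {n_voxels}); using all")
        n_voxels = len(score)
    top = np.argsort(score, kind="stable")[::-1][:n_voxels]
    coords = np.argwhere(mask)[top]
    return curves[top], coords


def select_aif(stack: CTPStack, n_voxels: int = 100, return_voxels: bool = False):
    """Automatic AIF: average curve of the ``n_voxels`` best arterial candidates.

    Candidates are ranked by a score favoring high peak enhancement and early
    time-to-peak; the returned curve is baseline-subtracted and clipped at 0.
    """
    curves, coords = _rank_curves(stack, n_voxels, late=False)
    aif = AIFCurve(times=stack.times,
                   values=np.clip(curves.mean(axis=0), 0.0, None))
    return (aif, coords) if return_voxels else aif


def select_vof(stack: CTPStack, n_voxels: int = 100, return_voxels: bool = False):
    """Automatic VOF: like the AIF but favoring late time-to-peak."""
    curves, coords = _rank_curves(stack, n_voxels, late=True)
    vof = AIFCurve(times=stack.times,
                   values=np.clip(curves.mean(axis=0), 0.0, None))
    return (vof, coords) if return_voxels else vof


def compute_maps(stack: CTPStack, aif: AIFCurve | None = None,
                 config: NLRConfig | None = None,
                 return_details: bool = False):
    """Fit every brain-mask voxel and assemble the parameter maps.

    Maps are zero outside the mask.  Deterministic given inputs; pass
    ``return_details=True`` to also get the SSE volume and fit flags.
    """
    cfg = config or NLRConfig()
    mask = stack.brain_mask
    if mask is None:
        mask = derive_brain_mask(stack, cfg.mask_threshold_hu)
    if not mask.any():
        raise ValueError("empty brain mask")
    if aif is None:
        aif = select_aif(stack)

    k = _arrival_index(aif.values, cfg.arrival_fraction)
    curves = _baseline_subtracted(stack, k)[mask]
    fit = fit_voxels(curves, aif, config=cfg)

    shape = stack.spatial_shape
    maps = {}
    for name, key in (("cbf", "cbf"), ("cbv", "cbv"), ("mtt", "mtt"),
                      ("ttp", "delay")):
        vol = np.zeros(shape)
        vol[mask] = fit[key]
        maps[name] = vol
    result = ParamMaps(maps, cfg.norm_constants)
    if return_details:
        sse = np.zeros(shape)
        sse[mask] = fit["sse"]
        return result, {"sse": sse, "flag": fit["flag"], "mask": mask}
    return result
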