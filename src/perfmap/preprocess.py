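"""Pre-processing: rigid motion correction and guided 3-D bilateral filtering.

Frames are registered to the first frame by minimizing the sum of squared
differences with a stochastic gradient scheme, coarse-to-fine (default 8x
down-sampling then full resolution, 2,000 / 8,000 random samples and 300
iterations per level).  The bilateral filter runs per frame with weights
computed once from the temporal-mean guide volume (spatial sd 3 mm, range
sd 20 HU by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .core import CTPStack

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "register_frames",
    "apply_rigid",
    "bilateral_filter_4d",
    "preprocess_stack",
]


@dataclass
class RigidTransform:
    rotation_deg: tuple = (0.0, 0.0, 0.0)
    translation_mm: tuple = (0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return (all(r == 0 for r in self.rotation_deg)
                and all(t == 0 for t in self.translation_mm))

    def to_dict(self):
        return {"rotation_deg": list(self.rotation_deg),
                "translation_mm": list(self.translation_mm)}


@dataclass
class RegistrationConfig:
    levels: tuple = (8, 1)              # per-level down-sampling factors
    samples: tuple = (2000, 8000)       # random samples per iteration
    iterations: tuple = (300, 300)      # SGD iterations per level
    step_mm: float = 0.4                # initial step length
    step_decay: float = 60.0            # iterations to halve the step
    seed: int = 0

    def __post_init__(self):
        if not (len(self.levels) == len(self.samples) == len(self.iterations)):
            raise ValueError("levels, samples and iterations must align")


def _rotation_matrix(angles):
    rx, ry, rz = angles
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _rotation_derivs(angles, h=1e-5):
    # numerical derivative of R wrt each Euler angle; plenty accurate for SGD
    derivs = []
    for i in range(3):
        a_p = list(angles); a_p[i] += h
        a_m = list(angles); a_m[i] -= h
        derivs.append((_rotation_matrix(a_p) - _rotation_matrix(a_m)) / (2 * h))
    return derivs


def _downsample(vol, spacing, factor):
    if factor <= 1:
        return vol, spacing
    factors, out_spacing = [], []
    for dim, sp in zip(vol.shape, spacing):
        f = min(factor, max(1, dim // 4))
        factors.append(1.0 / f)
        out_spacing.append(sp * f)
    sm = [0.5 * (1 / z) if z < 1 else 0.0 for z in factors]
    vol = ndi.gaussian_filter(vol, sigma=sm)
    return ndi.zoom(vol, factors, order=1), tuple(out_spacing)


def _sgd_level(fixed, moving, spacing, p, n_samples, n_iter, step_mm,
               step_decay, rng):
    """Refine rigid params p = (rx, ry, rz rad, tx, ty, tz mm) on one level.

    Gradient descent on the SSD over a random voxel sample that is drawn
    once per level (seeded), so the objective is fixed and the iteration
    converges instead of random-walking on sampling noise.  The gradient is
    rescaled by an image-derived normalizer (residual scale x RMS spatial
    gradient), so a full-contrast misalignment moves ~``step_mm`` per
    iteration while an aligned pair only sees noise-sized steps.
    """
    shape = np.array(fixed.shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    center = (shape - 1) / 2.0 * spacing
    grads = np.gradient(moving, *spacing)
    r_ref = max(float(np.mean((shape - 1) * spacing) / 4.0), 1e-6)
    rms_grad = float(np.sqrt(np.mean(sum(g * g for g in grads))))
    sigma = float(fixed.std())
    norm = 2.0 * rms_grad * sigma + 1e-12

    pts = rng.uniform(0.0, shape - 1, size=(n_samples, 3))
    fvals = ndi.map_coordinates(fixed, pts.T, order=1)
    X0 = pts * spacing - center

    for k in range(n_iter):
        X = X0
        R = _rotation_matrix(p[:3])
        Xm = X @ R.T + p[3:]
        vox = (Xm + center) / spacing
        mvals = ndi.map_coordinates(moving, vox.T, order=1, cval=0.0)
        gm = np.stack([ndi.map_coordinates(g, vox.T, order=1, cval=0.0)
                       for g in grads])            # (3, N) mm-gradient
        e = mvals - fvals
        g = np.empty(6)
        g[3:] = 2.0 / n_samples * gm @ e
        for i, dR in enumerate(_rotation_derivs(p[:3])):
            dX = X @ dR.T                           # (N, 3)
            g[i] = 2.0 / n_samples * np.einsum("n,jn,nj->", e, gm, dX) / r_ref
        upd = (step_mm / (1.0 + k / step_decay)) * g / norm
        p[3:] -= upd[3:]
        p[:3] -= upd[:3] / r_ref
    return p


def apply_rigid(frame, transform: RigidTransform, spacing):
    """Resample one frame under a rigid transform (linear interp, zero fill)."""
    angles = np.deg2rad(transform.rotation_deg)
    R = _rotation_matrix(angles)
    S = np.diag(spacing)
    Sinv = np.diag(1.0 / np.asarray(spacing, dtype=float))
    shape = np.array(frame.shape, dtype=float)
    center = (shape - 1) / 2.0 * np.asarray(spacing, dtype=float)
    A = Sinv @ R @ S
    b = Sinv @ (R @ (-center) + np.asarray(transform.translation_mm) + center)
    return ndi.affine_transform(frame, A, offset=b, order=1, mode="constant",
                                cval=0.0)


def register_frames(stack: CTPStack, config: RegistrationConfig | None = None):
    """Align every frame to frame 0; returns (registered stack, transforms).

    Frame 0 is untouched and its transform is the identity.  Constant
    (degenerate) frames produce a warning and keep the identity transform.
    """
    cfg = config or RegistrationConfig()
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to register")
    fixed_full = np.asarray(stack.data[..., 0], dtype=float)
    spacing = stack.voxel_spacing
    rng = np.random.default_rng(cfg.seed)

    pyramid = [_downsample(fixed_full, spacing, f) for f in cfg.levels]
    out = np.empty_like(stack.data, dtype=float)
    out[..., 0] = stack.data[..., 0]
    transforms = [RigidTransform()]

    for f in range(1, stack.n_frames):
        moving_full = np.asarray(stack.data[..., f], dtype=float)
        if np.ptp(moving_full) == 0 or np.ptp(fixed_full) == 0:
            warnings.warn(f"frame {f}: constant image, keeping identity")
            out[..., f] = moving_full
            transforms.append(RigidTransform())
            continue
        p = np.zeros(6)
        for (fix_l, sp_l), factor, n_s, n_i in zip(
                pyramid, cfg.levels, cfg.samples, cfg.iterations):
            mov_l, _ = _downsample(moving_full, spacing, factor)
            p = _sgd_level(fix_l, mov_l, sp_l, p, n_s, n_i,
                           cfg.step_mm * factor, cfg.step_decay, rng)
        tr = RigidTransform(rotation_deg=tuple(np.rad2deg(p[:3])),
                            translation_mm=tuple(p[3:]))
        out[..., f] = apply_rigid(moving_full, tr, spacing)
        transforms.append(tr)

    reg = CTPStack(data=out, times=stack.times.copy(), voxel_spacing=spacing,
                   brain_mask=None if stack.brain_mask is None
                   else stack.brain_mask.copy())
    return reg, transforms


def bilateral_filter_4d(stack: CTPStack, spatial_sd_mm: float = 3.0,
                        range_sd_hu: float = 20.0,
                        truncate: float = 3.0) -> CTPStack:
    """Edge-preserving smoothing of every frame, guided by the temporal mean.

    Weights combine a spatial Gaussian (sd ``spatial_sd_mm``) with a range
    Gaussian on guide-value differences (sd ``range_sd_hu``); because the
    guide is shared by all frames, each neighbor offset is weighted once and
    applied to the whole time series.  Kernels are truncated at
    ``truncate`` spatial standard deviations.
    """
    if spatial_sd_mm <= 0 or range_sd_hu <= 0:
        raise ValueError("kernel standard deviations must be positive")
    data = np.asarray(stack.data, dtype=float)
    spacing = np.asarray(stack.voxel_spacing, dtype=float)
    guide = data.mean(axis=3)

    radius_mm = truncate * spatial_sd_mm
    radii = [min(int(np.floor(radius_mm / sp)), n - 1)
             for sp, n in zip(spacing, guide.shape)]
    num = np.zeros_like(data)
    den = np.zeros(guide.shape)

    for dx in range(-radii[0], radii[0] + 1):
        for dy in range(-radii[1], radii[1] + 1):
            for dz in range(-radii[2], radii[2] + 1):
                d2 = ((dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2
                      + (dz * spacing[2]) ** 2)
                if d2 > radius_mm ** 2:
                    continue
                w_sp = np.exp(-0.5 * d2 / spatial_sd_mm ** 2)
                src = tuple(slice(max(0, -d), min(n, n - d))
                            for d, n in zip((dx, dy, dz), guide.shape))
                dst = tuple(slice(max(0, d), min(n, n + d))
                            for d, n in zip((dx, dy, dz), guide.shape))
                gdiff = guide[dst] - guide[src]
                w = w_sp * np.exp(-0.5 * (gdiff / range_sd_hu) ** 2)
                den[dst] += w
                num[dst] += w[..., None] * data[src]

    out = num / den[..., None]
    return CTPStack(data=out, times=stack.times.copy(),
                    voxel_spacing=stack.voxel_spacing,
                    brain_mask=None if stack.brain_mask is None
                    else stack.brain_mask.copy())


def preprocess_stack(stack: CTPStack, register: bool = True,
                     reg_config: RegistrationConfig | None = None,
                     spatial_sd_mm: float = 3.0, range_sd_hu: float = 20.0):
    """Registration (optional) followed by guided bilateral filtering."""
    transforms = None
    if register:
        stack, transforms = register_frames(stack, reg_config)
    filtered = bilateral_filter_4d(stack, spatial_sd_mm, range_sd_hu)
    return filtered, transforms
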