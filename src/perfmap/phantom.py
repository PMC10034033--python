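"""Digital perfusion phantom: 4-D CTP stacks with known per-voxel parameters.

A phantom is a cylindrical "brain" of normal tissue containing an artery,
an optional spherical ischemic core with a surrounding penumbra shell, and
air outside.  Tissue curves follow the box-IRF forward model in
:mod:`perfmap.model`; artery voxels carry the bolus curve directly.  The
default protocol mirrors a 44.5 s / 89-volume acquisition scaled to a desk
grid (64x64x4 voxels, 32 frames).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .core import AIFCurve, CTPStack, ParamMaps
from .model import gamma_variate_aif, tissue_curve

__all__ = [
    "PhantomSpec",
    "GroundTruthBundle",
    "LABELS",
    "region_mask",
    "region_labels",
    "make_param_maps",
    "synthesize_ctp",
    "make_phantom",
    "generate_cohort",
]

LABELS = {"background": 0, "normal": 1, "penumbra": 2, "core": 3, "artery": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


class InvalidSpecError(ValueError):
    pass


def _default_regions():
    return {
        "normal": {"kind": "cylinder", "center_mm": (96.0, 96.0), "radius_mm": 80.0},
        "artery": {"kind": "cylinder", "center_mm": (96.0, 48.0), "radius_mm": 10.0},
        "core": {"kind": "sphere", "center_mm": (60.0, 120.0, 10.0), "radius_mm": 18.0},
        "penumbra": {"kind": "shell", "center_mm": (60.0, 120.0, 10.0),
                     "inner_radius_mm": 18.0, "outer_radius_mm": 30.0},
    }


def _default_tissue_params():
    # (CBF mL/100g/min, MTT s, delay s) per region
    return {
        "normal": (60.0, 5.0, 2.0),
        "penumbra": (28.0, 8.0, 4.0),
        "core": (10.0, 12.0, 6.0),
        "artery": (100.0, 4.0, 0.5),
    }


def _default_aif_params():
    return {"t0": 4.0, "alpha": 3.0, "beta": 3.2, "amplitude": 350.0}


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 64, 4)
    voxel_spacing: tuple = (3.0, 3.0, 5.0)   # mm
    n_frames: int = 32
    duration: float = 44.5                    # s
    baseline_hu: float = 40.0                 # brain tissue before contrast
    air_hu: float = 0.0                       # outside the head
    noise_sd: float = 2.0                     # HU
    texture_sd_hu: float = 0.0                # static anatomical texture
    skull_hu: float = 0.0                     # 0 disables the skull ring
    skull_thickness_mm: float = 6.0
    #: smooth bolus-arrival ramp across the brain: extra delay (s) grows
    #: linearly along ``delay_ramp_deg`` up to this value at the far edge
    delay_ramp_s: float = 0.0
    delay_ramp_deg: float = 0.0
    #: optional delayed-arrival territories: spherical regions of extra
    #: bolus delay (variable collateral supply), independent of the CBF
    #: lesion geometry; each is {center_mm, radius_mm, extra_delay_s}
    delay_territories: list | None = None
    #: voxel-scale bolus-arrival heterogeneity (s): a seeded, locally
    #: correlated random delay field added to all tissue
    delay_jitter_sd_s: float = 0.0
    regions: dict = field(default_factory=_default_regions)
    tissue_params: dict = field(default_factory=_default_tissue_params)
    aif_params: dict = field(default_factory=_default_aif_params)
    motion: list | None = None                # per-frame {"shift_mm", "rot_deg"}
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise InvalidSpecError("need at least 2 frames")
        if self.duration <= 0:
            raise InvalidSpecError("duration must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        for name, (cbf, mtt, delay) in self.tissue_params.items():
            if cbf < 0 or mtt <= 0 or delay < 0:
                raise InvalidSpecError(
                    f"region {name!r}: need CBF >= 0, MTT > 0, delay >= 0")
        if self.motion is not None and len(self.motion) != self.n_frames:
            raise InvalidSpecError("motion must list one transform per frame")
        regions = {}
        for name, desc in self.regions.items():
            if desc is not None:
                desc = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                        for k, v in desc.items()}
            regions[name] = desc
        self.regions = regions

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times; n_frames over duration (uniform)."""
        return np.arange(self.n_frames) * (self.duration / self.n_frames)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_spacing"] = list(self.voxel_spacing)
        d["tissue_params"] = {k: list(v) for k, v in self.tissue_params.items()}
        d["regions"] = {
            name: None if desc is None else
            {k: list(v) if isinstance(v, tuple) else v for k, v in desc.items()}
            for name, desc in self.regions.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_spacing"] = tuple(d["voxel_spacing"])
        if "tissue_params" in d:
            d["tissue_params"] = {k: tuple(v) for k, v in d["tissue_params"].items()}
        return cls(**d)


@dataclass
class GroundTruthBundle:
    stack: CTPStack
    true_maps: ParamMaps
    region_labels: np.ndarray
    aif: AIFCurve
    spec: PhantomSpec | None = None

    def __post_init__(self):
        shape = self.stack.spatial_shape
        if self.true_maps.shape != shape or self.region_labels.shape != shape:
            raise ValueError("bundle components must share the spatial grid")


def _voxel_centers(grid_shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def region_mask(desc: dict, grid_shape, spacing) -> np.ndarray:
    """Boolean mask of a geometric region descriptor (mm coordinates)."""
    x, y, z = _voxel_centers(grid_shape, spacing)
    kind = desc["kind"]
    c = desc["center_mm"]
    if kind == "cylinder":  # axis along z, full extent
        r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2
        return r2 <= desc["radius_mm"] ** 2
    if kind == "sphere":
        r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        return r2 <= desc["radius_mm"] ** 2
    if kind == "shell":
        r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        return (r2 > desc["inner_radius_mm"] ** 2) & (r2 <= desc["outer_radius_mm"] ** 2)
    if kind == "box":
        size = desc["size_mm"]
        return ((np.abs(x - c[0]) <= size[0] / 2)
                & (np.abs(y - c[1]) <= size[1] / 2)
                & (np.abs(z - c[2]) <= size[2] / 2))
    raise InvalidSpecError(f"unknown region kind {kind!r}")


def region_labels(spec: PhantomSpec) -> np.ndarray:
    """Integer label volume; overlapping lesion/artery regions are an error."""
    if "normal" not in spec.regions:
        raise InvalidSpecError("spec must define a 'normal' (brain) region")
    brain = region_mask(spec.regions["normal"], spec.grid_shape, spec.voxel_spacing)
    if not brain.any():
        raise InvalidSpecError("brain region is empty")
    labels = np.where(brain, LABELS["normal"], LABELS["background"]).astype(np.int16)
    special = [n for n in ("penumbra", "core", "artery")
               if spec.regions.get(n) is not None]
    masks = {n: region_mask(spec.regions[n], spec.grid_shape, spec.voxel_spacing)
             for n in special}
    for i, a in enumerate(special):
        for b in special[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise InvalidSpecError(f"regions {a!r} and {b!r} overlap")
    for name in special:
        m = masks[name]
        if np.any(m & ~brain):
            raise InvalidSpecError(f"region {name!r} extends outside the brain")
        labels[m] = LABELS[name]
    return labels


def make_param_maps(spec: PhantomSpec):
    """Ground-truth parameter maps from the region geometry.

    Returns ``(ParamMaps, labels)``.  Each voxel carries its region's
    (CBF, MTT, delay); CBV follows from the central volume principle;
    background voxels have zero flow.
    """
    labels = region_labels(spec)
    shape = labels.shape
    cbf = np.zeros(shape)
    mtt = np.ones(shape)  # nominal positive MTT where flow is zero
    ttp = np.zeros(shape)
    for name, lab in LABELS.items():
        if name == "background":
            continue
        params = spec.tissue_params.get(name)
        if params is None:
            continue
        m = labels == lab
        cbf[m], mtt[m], ttp[m] = params
    if spec.delay_ramp_s > 0:
        # bolus arrival drifts smoothly across the brain (collateral-flow
        # style); excludes the artery, whose curve is the input function
        brain_desc = spec.regions["normal"]
        x, y, _ = _voxel_centers(shape, spec.voxel_spacing)
        ang = np.deg2rad(spec.delay_ramp_deg)
        proj = ((x - brain_desc["center_mm"][0]) * np.cos(ang)
                + (y - brain_desc["center_mm"][1]) * np.sin(ang))
        ramp = spec.delay_ramp_s * np.clip(
            0.5 + proj / (2.0 * brain_desc["radius_mm"]), 0.0, 1.0)
        tissue = (labels > 0) & (labels != LABELS["artery"])
        ttp[tissue] += ramp[tissue]
    if spec.delay_territories:
        # overlapping territories do not stack: arrival is set by the
        # fastest collateral route, so the dominant (max) delay wins
        extra_field = np.zeros(shape)
        for territory in spec.delay_territories:
            dt_desc = dict(territory)
            extra = float(dt_desc.pop("extra_delay_s"))
            m = region_mask({"kind": "sphere", **dt_desc}, shape,
                            spec.voxel_spacing)
            np.maximum(extra_field, np.where(m, extra, 0.0), out=extra_field)
        tissue = (labels > 0) & (labels != LABELS["artery"])
        ttp[tissue] += extra_field[tissue]
    if spec.delay_jitter_sd_s > 0:
        # capillary/arteriolar arrival heterogeneity at the voxel scale;
        # the positive tail is capped so jitter alone cannot mimic a
        # delayed-arrival (hypoperfused) territory
        jrng = np.random.default_rng((spec.seed, 29))
        jit = ndi.gaussian_filter(jrng.normal(size=shape), sigma=(0.6, 0.6, 0.3))
        jit *= spec.delay_jitter_sd_s / max(jit.std(), 1e-12)
        np.minimum(jit, 1.8, out=jit)
        tissue = (labels > 0) & (labels != LABELS["artery"])
        ttp[tissue] = np.maximum(ttp[tissue] + jit[tissue], 0.0)
    cbv = cbf * mtt / 60.0
    maps = ParamMaps({"cbf": cbf, "cbv": cbv, "mtt": mtt, "ttp": ttp})
    return maps, labels


def _apply_rigid_frame(frame, shift_mm, rot_deg, spacing):
    """Resample one frame under a rigid motion (linear interp, zero fill)."""
    out = frame
    if any(abs(r) > 0 for r in rot_deg):
        # rotations about each axis, in-plane first; small angles expected
        for axes, ang in (((0, 1), rot_deg[2]), ((0, 2), rot_deg[1]),
                          ((1, 2), rot_deg[0])):
            if abs(ang) > 0:
                out = ndi.rotate(out, ang, axes=axes, reshape=False,
                                 order=1, mode="constant", cval=0.0)
    shift_vox = [s / sp for s, sp in zip(shift_mm, spacing)]
    if any(abs(s) > 0 for s in shift_vox):
        out = ndi.shift(out, shift_vox, order=1, mode="constant", cval=0.0)
    return out


def synthesize_ctp(true_maps: ParamMaps, aif: AIFCurve,
                   spec: PhantomSpec) -> GroundTruthBundle:
    """Render the 4-D stack implied by ``true_maps`` under the forward model.

    Tissue voxels get ``baseline + tissue_curve``; artery voxels get
    ``baseline + AIF``; i.i.d. Gaussian noise (``spec.noise_sd``) and the
    optional per-frame rigid motion are applied afterwards.
    """
    labels = region_labels(spec)
    times = spec.times
    shape = labels.shape
    data = np.empty(shape + (spec.n_frames,), dtype=float)
    data[:] = spec.air_hu
    data[labels > 0] = spec.baseline_hu

    if spec.skull_hu > 0:
        # static bone ring just outside the brain; not part of the brain
        # mask, but it anchors frame-to-frame registration like a real skull
        brain_desc = spec.regions["normal"]
        outer = dict(brain_desc)
        outer["radius_mm"] = brain_desc["radius_mm"] + spec.skull_thickness_mm
        skull = region_mask(outer, spec.grid_shape, spec.voxel_spacing) \
            & (labels == 0)
        data[skull] = spec.skull_hu

    if spec.texture_sd_hu > 0:
        # static smooth pseudo-anatomy, constant over time; it cancels in
        # baseline subtraction but gives registration something to grip
        trng = np.random.default_rng((spec.seed, 17))
        tex = ndi.gaussian_filter(trng.normal(size=shape), sigma=1.5)
        tex /= max(tex[labels > 0].std(), 1e-12)
        data[labels > 0] += (spec.texture_sd_hu * tex[labels > 0])[:, None]

    params = np.stack([true_maps["cbf"], true_maps["mtt"], true_maps["ttp"]],
                      axis=-1).reshape(-1, 3)
    flat = data.reshape(-1, spec.n_frames)
    tissue = (labels != LABELS["artery"]).reshape(-1)
    uniq, inv = np.unique(params[tissue], axis=0, return_inverse=True)
    curves = np.zeros((len(uniq), spec.n_frames))
    for i, (c, m, d) in enumerate(uniq):
        if c > 0:
            curves[i] = tissue_curve(aif, c, m, d, times)
    flat[tissue] += curves[inv]
    flat[~tissue] += aif.values

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    if spec.motion is not None:
        for f, mo in enumerate(spec.motion):
            shift = tuple(mo.get("shift_mm", (0.0, 0.0, 0.0)))
            rot = tuple(mo.get("rot_deg", (0.0, 0.0, 0.0)))
            data[..., f] = _apply_rigid_frame(data[..., f], shift, rot,
                                             spec.voxel_spacing)

    stack = CTPStack(data=data, times=times, voxel_spacing=spec.voxel_spacing,
                     brain_mask=labels > 0)
    return GroundTruthBundle(stack=stack, true_maps=true_maps,
                             region_labels=labels, aif=aif, spec=spec)


def make_phantom(spec: PhantomSpec) -> GroundTruthBundle:
    """Full phantom build: AIF + parameter maps + rendered stack."""
    aif = gamma_variate_aif(spec.aif_params, spec.times)
    maps, _ = make_param_maps(spec)
    return synthesize_ctp(maps, aif, spec)


def generate_cohort(n_subjects: int, seed: int,
                    base_spec: PhantomSpec | None = None,
                    lesion_fraction: float = 1.0 / 3.0) -> list[GroundTruthBundle]:
    """A cohort of randomized phantoms; ~``lesion_fraction`` carry lesions.

    Per subject the lesion geometry, regional perfusion values, a global
    bolus-delay offset and the bolus shape are jittered (seeded), so maps
    differ across subjects in both geometry and quantitative level.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base = base_spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects + 1)
    rng = np.random.default_rng(children[-1])
    n_lesioned = int(round(n_subjects * lesion_fraction))
    lesioned = np.zeros(n_subjects, dtype=bool)
    lesioned[rng.choice(n_subjects, size=n_lesioned, replace=False)] = True

    bundles = []
    for i in range(n_subjects):
        r = np.random.default_rng(children[i])
        regions = {k: dict(v) for k, v in base.regions.items()}
        tp = dict(base.tissue_params)
        delay_offset = r.uniform(0.0, 3.0)
        for name in ("normal", "penumbra", "core", "artery"):
            cbf, mtt, dly = tp[name]
            tp[name] = (cbf * r.uniform(0.9, 1.1),
                        mtt * r.uniform(0.9, 1.1),
                        dly + delay_offset)
        if not lesioned[i]:
            regions["core"] = None
            regions["penumbra"] = None
        aif = dict(base.aif_params)
        aif["t0"] = r.uniform(3.0, 6.0)
        aif["amplitude"] = r.uniform(0.88, 1.12) * base.aif_params["amplitude"]
        ramp_s = r.uniform(1.0, 2.0)
        ramp_deg = r.uniform(0.0, 360.0)
        # arrival-delay patches: subject-specific timing structure with
        # sub-threshold amplitudes (they shape the TTP map, not the
        # hypoperfusion segmentation)
        brain = regions["normal"]
        territories = []
        for _ in range(int(r.integers(2, 5))):
            pang = r.uniform(0, 2 * np.pi)
            pdist = brain["radius_mm"] * r.uniform(0.0, 0.7)
            territories.append({
                "center_mm": (brain["center_mm"][0] + pdist * np.cos(pang),
                              brain["center_mm"][1] + pdist * np.sin(pang),
                              base.voxel_spacing[2] * base.grid_shape[2] / 2.0),
                "radius_mm": r.uniform(12.0, 30.0),
                "extra_delay_s": r.uniform(0.6, 1.2),
            })
        for _attempt in range(64):
            if lesioned[i]:
                brain = regions["normal"]
                rb = brain["radius_mm"]  # lesion geometry scales with brain
                ang = r.uniform(0, 2 * np.pi)
                dist = rb * r.uniform(0.25, 0.45)
                cx = brain["center_mm"][0] + dist * np.cos(ang)
                cy = brain["center_mm"][1] + dist * np.sin(ang)
                cz = base.voxel_spacing[2] * base.grid_shape[2] / 2.0
                r_core = rb * r.uniform(0.22, 0.32)
                r_pen = r_core + rb * r.uniform(0.10, 0.18)
                regions["core"] = {"kind": "sphere", "center_mm": (cx, cy, cz),
                                   "radius_mm": r_core}
                regions["penumbra"] = {"kind": "shell", "center_mm": (cx, cy, cz),
                                       "inner_radius_mm": r_core,
                                       "outer_radius_mm": r_pen}
                # mismatch-style arrival-delay territory around the lesion,
                # still below the hypoperfusion TTP threshold
                off = r.uniform(8.0, 18.0)
                oang = r.uniform(0, 2 * np.pi)
                territories = territories[:2] + [{
                    "center_mm": (cx + off * np.cos(oang),
                                  cy + off * np.sin(oang), cz),
                    "radius_mm": r_pen * r.uniform(1.2, 1.5),
                    "extra_delay_s": r.uniform(1.0, 1.8),
                }]
            spec = dataclasses.replace(
                base, regions=regions, tissue_params=tp, aif_params=aif,
                delay_ramp_s=ramp_s, delay_ramp_deg=ramp_deg,
                delay_territories=territories,
                delay_jitter_sd_s=base.delay_jitter_sd_s or 1.6,
                seed=int(np.random.default_rng(children[i]).integers(2 ** 31)))
            try:
                bundles.append(make_phantom(spec))
                break
            except InvalidSpecError:
                if not lesioned[i]:
                    raise  # nothing random left to retry
        else:
            raise InvalidSpecError("could not place a lesion inside the brain")
    return bundles
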