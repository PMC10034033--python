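"""NIfTI and sidecar I/O for stacks, maps and phantom bundles."""
from __future__ import annotations

import json
import os
import tempfile

import nibabel as nib
import numpy as np
import yaml

from .core import AIFCurve, CTPStack, ParamMaps
from .phantom import GroundTruthBundle, PhantomSpec

__all__ = [
    "save_stack",
    "load_stack",
    "save_maps",
    "load_maps",
    "save_bundle",
    "load_bundle",
    "atomic_write_text",
]


def atomic_write_text(path, text: str):
    """Write a text file atomically (temp file + rename)."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _affine(spacing):
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_stack(stack: CTPStack, path):
    """4-D NIfTI with the time grid in a JSON sidecar next to it."""
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float32),
                          _affine(stack.voxel_spacing))
    img.header.set_zooms(stack.voxel_spacing
                         + (float(np.diff(stack.times).mean()),))
    nib.save(img, path)
    side = {"times_s": stack.times.tolist()}
    atomic_write_text(_sidecar(path), json.dumps(side))
    if stack.brain_mask is not None:
        nib.save(nib.Nifti1Image(stack.brain_mask.astype(np.uint8),
                                 _affine(stack.voxel_spacing)),
                 _mask_path(path))


def _sidecar(path):
    return _strip_nii(path) + ".json"


def _mask_path(path):
    return _strip_nii(path) + "_mask.nii.gz"


def _strip_nii(path):
    path = os.fspath(path)
    for ext in (".nii.gz", ".nii"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


def load_stack(path) -> CTPStack:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    sidecar = _sidecar(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            times = np.asarray(json.load(fh)["times_s"], dtype=float)
    else:
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        times = np.arange(data.shape[3]) * dt
    mask = None
    mp = _mask_path(path)
    if os.path.exists(mp):
        mask = np.asarray(nib.load(mp).dataobj) > 0
    return CTPStack(data=data, times=times, voxel_spacing=spacing,
                    brain_mask=mask)


def save_maps(maps: ParamMaps, out_dir, prefix="", spacing=(1.0, 1.0, 1.0)):
    """One 3-D NIfTI per parameter plus a JSON of normalization constants."""
    os.makedirs(out_dir, exist_ok=True)
    for name in maps.names:
        nib.save(nib.Nifti1Image(maps[name].astype(np.float32),
                                 _affine(spacing)),
                 os.path.join(out_dir, f"{prefix}{name}.nii.gz"))
    atomic_write_text(os.path.join(out_dir, f"{prefix}norm.json"),
                      json.dumps(maps.norm_constants))


def load_maps(out_dir, prefix="") -> ParamMaps:
    with open(os.path.join(out_dir, f"{prefix}norm.json")) as fh:
        norm = json.load(fh)
    vols = {}
    for name in ("cbf", "cbv", "mtt", "ttp"):
        p = os.path.join(out_dir, f"{prefix}{name}.nii.gz")
        if os.path.exists(p):
            vols[name] = np.asarray(nib.load(p).dataobj, dtype=float)
    if not vols:
        raise FileNotFoundError(f"no parameter maps under {out_dir}")
    return ParamMaps(vols, norm)


def save_bundle(bundle: GroundTruthBundle, out_dir):
    """Stack + true maps + labels + AIF + spec, ready for reload."""
    os.makedirs(out_dir, exist_ok=True)
    spacing = bundle.stack.voxel_spacing
    save_stack(bundle.stack, os.path.join(out_dir, "stack.nii.gz"))
    save_maps(bundle.true_maps, out_dir, prefix="true_", spacing=spacing)
    nib.save(nib.Nifti1Image(bundle.region_labels.astype(np.int16),
                             _affine(spacing)),
             os.path.join(out_dir, "labels.nii.gz"))
    side = {"aif_times_s": bundle.aif.times.tolist(),
            "aif_values_hu": bundle.aif.values.tolist()}
    atomic_write_text(os.path.join(out_dir, "aif.json"), json.dumps(side))
    if bundle.spec is not None:
        atomic_write_text(os.path.join(out_dir, "spec.yaml"),
                          yaml.safe_dump(bundle.spec.to_dict()))


def load_bundle(out_dir) -> GroundTruthBundle:
    stack = load_stack(os.path.join(out_dir, "stack.nii.gz"))
    maps = load_maps(out_dir, prefix="true_")
    labels = np.asarray(nib.load(os.path.join(out_dir, "labels.nii.gz")).dataobj)
    with open(os.path.join(out_dir, "aif.json")) as fh:
        side = json.load(fh)
    aif = AIFCurve(times=np.asarray(side["aif_times_s"], dtype=float),
                   values=np.asarray(side["aif_values_hu"], dtype=float))
    spec = None
    spec_path = os.path.join(out_dir, "spec.yaml")
    if os.path.exists(spec_path):
        with open(spec_path) as fh:
            spec = PhantomSpec.from_dict(yaml.safe_load(fh))
    return GroundTruthBundle(stack=stack, true_maps=maps,
                             region_labels=labels.astype(np.int16),
                             aif=aif, spec=spec)
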