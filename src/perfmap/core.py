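"""Core data containers shared across the pipeline.

Arrays are plain numpy; containers validate the few invariants the rest of
the code relies on (consistent grids, positive spacing, monotone time axes).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AIFCurve",
    "CTPStack",
    "ParamMaps",
    "PerfusionParams",
    "LesionMasks",
    "DEFAULT_NORM_CONSTANTS",
]

#: Fixed full-scale values used to map physical units onto [0, 1] so that
#: network targets and ground-truth maps share one scale.
DEFAULT_NORM_CONSTANTS: Mapping[str, float] = {
    "cbf": 120.0,  # mL/100g/min
    "cbv": 12.0,   # mL/100g
    "mtt": 30.0,   # s
    "ttp": 20.0,   # s
}

MAP_NAMES = ("cbf", "cbv", "mtt", "ttp")


@dataclass(frozen=True)
class AIFCurve:
    """Baseline-subtracted arterial time-attenuation curve on a time grid."""

    times: np.ndarray   # s, strictly increasing
    values: np.ndarray  # HU above baseline, >= 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(v < -1e-9):
            raise ValueError("AIF values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def time_to_peak(self) -> float:
        return float(self.times[int(np.argmax(self.values))])


@dataclass
class CTPStack:
    """4-D attenuation volume (X, Y, Z, t) in Hounsfield units."""

    data: np.ndarray
    times: np.ndarray          # s, one per frame
    voxel_spacing: tuple       # mm per axis (x, y, z)
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("CTP stack must be 4-D (X, Y, Z, t)")
        if self.data.shape[3] != self.times.shape[0]:
            raise ValueError("number of frames must match the time grid")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be three positive values")
        self.voxel_spacing = spacing
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain mask must match the spatial grid")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def copy(self) -> "CTPStack":
        return CTPStack(
            data=self.data.copy(),
            times=self.times.copy(),
            voxel_spacing=self.voxel_spacing,
            brain_mask=None if self.brain_mask is None else self.brain_mask.copy(),
        )


@dataclass(frozen=True)
class PerfusionParams:
    """Fit result for a single voxel."""

    cbf: float   # mL/100g/min
    mtt: float   # s
    delay: float  # s; reported as the TTP map
    sse: float   # HU^2 residual of the fit
    flag: str = "ok"  # "ok" | "no-signal" | "truncated"

    @property
    def cbv(self) -> float:
        # central volume principle, mL/100g
        return self.cbf * self.mtt / 60.0


class ParamMaps:
    """Per-voxel perfusion parameter volumes, raw units plus a 0-1 view.

    Raw maps are stored in physical units; ``normalized()`` divides by the
    recorded full-scale constants and clips to [0, 1], ``denormalize()``
    inverts it (exact for in-range values).
    """

    def __init__(self, maps: Mapping[str, np.ndarray],
                 norm_constants: Mapping[str, float] | None = None):
        unknown = set(maps) - set(MAP_NAMES)
        if unknown:
            raise ValueError(f"unknown map names: {sorted(unknown)}")
        shapes = {m.shape for m in maps.values()}
        if len(shapes) != 1:
            raise ValueError("all maps must share one spatial grid")
        self._maps = {k: np.asarray(v, dtype=float) for k, v in maps.items()}
        self.norm_constants = dict(norm_constants or DEFAULT_NORM_CONSTANTS)

    def __contains__(self, name):
        return name in self._maps

    def __getitem__(self, name) -> np.ndarray:
        return self._maps[name]

    @property
    def names(self):
        return tuple(self._maps)

    @property
    def shape(self):
        return next(iter(self._maps.values())).shape

    def normalized(self, name: str) -> np.ndarray:
        return np.clip(self._maps[name] / self.norm_constants[name], 0.0, 1.0)

    def denormalize(self, name: str, arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr, dtype=float) * self.norm_constants[name]

    def copy(self) -> "ParamMaps":
        return ParamMaps({k: v.copy() for k, v in self._maps.items()},
                         self.norm_constants)


@dataclass
class LesionMasks:
    """Binary lesion volumes; penumbra is derived, never stored inconsistently."""

    core: np.ndarray
    hypoperfused: np.ndarray
    voxel_spacing: tuple

    def __post_init__(self):
        self.core = np.asarray(self.core, dtype=bool)
        self.hypoperfused = np.asarray(self.hypoperfused, dtype=bool)
        if self.core.shape != self.hypoperfused.shape:
            raise ValueError("core and hypoperfused masks must share a grid")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def penumbra(self) -> np.ndarray:
        return self.hypoperfused & ~self.core
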