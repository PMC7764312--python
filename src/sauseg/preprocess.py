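"""Template-space registration contract, zero padding and landmark-based
histogram standardization.

Registration is a pluggable backend: the package ships an identity backend
(for pre-registered or synthetic inputs) and a known-transform backend, and
accepts any callable ``backend(moving, template) -> RigidTransform``. The
numeric content here is the Nyul-style landmark standardization: decile
percentiles of the foreground (> 0) are learned across a training set and
new volumes are mapped onto the learned standard scale piecewise-linearly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .io_schema import LabelVolume, Volume3D

__all__ = [
    "HistogramLandmarks",
    "RigidTransform",
    "RegistrationError",
    "identity_backend",
    "known_transform_backend",
    "register_to_template",
    "resample_to_grid",
    "pad_volume",
    "crop_volume",
    "learn_landmarks",
    "standardize_intensity",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                       60.0, 70.0, 80.0, 90.0, 99.0)


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass
class RigidTransform:
    """Euler rotation (degrees, xyz order) + translation (mm), about a fixed
    world-space rotation center."""

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """4x4 world-to-world homogeneous matrix."""
        rot = Rotation.from_euler("xyz", self.angles_deg, degrees=True).as_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        m = np.eye(4)
        m[:3, :3] = rot
        m[:3, 3] = c - rot @ c + t
        return m

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", self.angles_deg, degrees=True)
        inv = rot.inv()
        m = self.matrix()
        m_inv = np.linalg.inv(m)
        c = np.asarray(self.center_mm)
        t_inv = m_inv[:3, 3] - (c - m_inv[:3, :3] @ c)
        return RigidTransform(tuple(inv.as_euler("xyz", degrees=True)),
                              tuple(t_inv), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other (matrix product self @ other)."""
        m = self.matrix() @ other.matrix()
        rot = Rotation.from_matrix(m[:3, :3])
        c = np.asarray(self.center_mm)
        t = m[:3, 3] - (c - m[:3, :3] @ c)
        return RigidTransform(tuple(rot.as_euler("xyz", degrees=True)),
                              tuple(t), self.center_mm)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (max(abs(a) for a in self.angles_deg) < tol
                and max(abs(t) for t in self.translation_mm) < tol)


def resample_to_grid(moving: Volume3D, target: Volume3D,
                     transform: RigidTransform, order: int = 1,
                     cval: float = 0.0) -> Volume3D:
    """Resample ``moving`` onto ``target``'s grid under a world-space rigid map.

    ``transform`` maps moving-space world coordinates to target-space world
    coordinates; voxels are pulled through its inverse.
    """
    # target voxel -> target world -> moving world -> moving voxel
    t_inv = np.linalg.inv(transform.matrix())
    vox_map = np.linalg.inv(moving.affine) @ t_inv @ target.affine
    matrix = vox_map[:3, :3]
    offset = vox_map[:3, 3]
    data = ndimage.affine_transform(moving.data.astype(np.float64), matrix,
                                    offset=offset, output_shape=target.shape,
                                    order=order, mode="constant", cval=cval)
    return Volume3D(data, target.spacing, target.affine.copy())


def identity_backend(moving: Volume3D, template: Volume3D) -> RigidTransform:
    """For inputs already in template space (phantoms, pre-registered data)."""
    return RigidTransform()


def known_transform_backend(transform: RigidTransform
                            ) -> Callable[[Volume3D, Volume3D], RigidTransform]:
    """Oracle backend returning a caller-supplied ground-truth transform."""

    def backend(moving: Volume3D, template: Volume3D) -> RigidTransform:
        return transform

    return backend


def register_to_template(moving: Volume3D, template: Volume3D,
                         backend: Callable[[Volume3D, Volume3D], RigidTransform],
                         ) -> tuple[Volume3D, RigidTransform]:
    """Estimate a rigid transform via the backend and resample onto the template.

    Returns the resampled volume and the transform (moving world -> template
    world), which is kept so segmentations can be mapped back to native space.
    """
    if backend is None:
        raise RegistrationError("no registration backend provided")
    try:
        transform = backend(moving, template)
    except Exception as exc:  # pragma: no cover - backend-specific
        raise RegistrationError(f"registration backend failed: {exc}") from exc
    if not isinstance(transform, RigidTransform):
        raise RegistrationError(
            f"backend returned {type(transform).__name__}, expected RigidTransform")
    if transform.is_identity() and moving.shape == template.shape:
        return Volume3D(moving.data.copy(), template.spacing,
                        template.affine.copy()), transform
    resampled = resample_to_grid(moving, template, transform, order=1)
    return resampled, transform


# ---------------------------------------------------------------------------
# padding


def pad_volume(v: Volume3D, pad: Sequence[int]) -> Volume3D:
    """Zero-pad symmetrically; world coordinates of original voxels unchanged."""
    pad = tuple(int(p) for p in pad)
    if len(pad) != 3 or any(p < 0 for p in pad):
        raise ValueError("pad must be 3 non-negative integers")
    if all(p == 0 for p in pad):
        return Volume3D(v.data.copy(), v.spacing, v.affine.copy())
    data = np.pad(v.data, tuple((p, p) for p in pad))
    affine = v.affine.copy()
    affine[:3, 3] = (v.affine @ np.array([-pad[0], -pad[1], -pad[2], 1.0]))[:3]
    return Volume3D(data, v.spacing, affine)


def crop_volume(v: Volume3D, pad: Sequence[int]) -> Volume3D:
    """Inverse of :func:`pad_volume`."""
    pad = tuple(int(p) for p in pad)
    sl = tuple(slice(p, s - p) for p, s in zip(pad, v.shape))
    data = v.data[sl].copy()
    affine = v.affine.copy()
    affine[:3, 3] = (v.affine @ np.array([*pad, 1.0]))[:3]
    return Volume3D(data, v.spacing, affine)


def crop_labels(lv: LabelVolume, pad: Sequence[int]) -> LabelVolume:
    pad = tuple(int(p) for p in pad)
    sl = tuple(slice(p, s - p) for p, s in zip(pad, lv.shape))
    affine = lv.affine.copy()
    affine[:3, 3] = (lv.affine @ np.array([*pad, 1.0]))[:3]
    return LabelVolume(lv.data[sl].copy(), lv.schema, lv.spacing, affine)


# ---------------------------------------------------------------------------
# histogram landmarks


@dataclass
class HistogramLandmarks:
    percentiles: tuple[float, ...]
    standard_scale: tuple[float, ...]
    floor: float = 0.0
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        s = np.asarray(self.standard_scale, dtype=float)
        if p.size != s.size:
            raise ValueError("percentiles and standard scale must align")
        if p.size < 2 or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing")
        if np.any(np.diff(s) < 0):
            raise ValueError("standard-scale values must be non-decreasing")
        if np.any(p <= 0) or np.any(p >= 100):
            raise ValueError("percentiles must lie in (0, 100)")
        self.percentiles = tuple(p)
        self.standard_scale = tuple(s)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "percentiles": list(self.percentiles),
            "standard_scale": list(self.standard_scale),
            "floor": self.floor, "ceiling": self.ceiling,
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "HistogramLandmarks":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["percentiles"]), tuple(d["standard_scale"]),
                   d.get("floor", 0.0), d.get("ceiling", 100.0))


def _foreground(v: Volume3D) -> np.ndarray:
    fg = v.data[v.data > 0]
    if fg.size == 0:
        raise ValueError("volume has empty foreground (no voxels > 0)")
    return fg.astype(np.float64)


def learn_landmarks(training_volumes: Sequence[Volume3D],
                    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                    standard_range: tuple[float, float] = (1.0, 100.0),
                    ) -> HistogramLandmarks:
    """Learn standard-scale landmark values from a training set.

    Each volume's foreground percentiles are mapped linearly so that
    [p_min, p_max] covers the standard range; the standard scale is the mean
    of the mapped percentiles over volumes. The default range starts at 1 so
    standardized foreground voxels stay strictly positive and the > 0
    foreground convention survives repeated standardization.
    """
    if len(training_volumes) == 0:
        raise ValueError("need at least one training volume")
    percentiles = tuple(float(p) for p in percentiles)
    lo, hi = standard_range
    mapped = np.zeros((len(training_volumes), len(percentiles)))
    for i, v in enumerate(training_volumes):
        fg = _foreground(v)
        p = np.percentile(fg, percentiles)
        if p[-1] <= p[0]:
            raise ValueError("degenerate (constant) foreground")
        mapped[i] = lo + (p - p[0]) * (hi - lo) / (p[-1] - p[0])
    return HistogramLandmarks(percentiles, tuple(mapped.mean(axis=0)),
                              floor=lo, ceiling=hi)


def standardize_intensity(v: Volume3D, lm: HistogramLandmarks) -> Volume3D:
    """Piecewise-linear map of foreground percentiles onto the standard scale.

    Monotone by construction; background (<= 0) voxels are left untouched;
    output clipped to [floor, ceiling].
    """
    fg_mask = v.data > 0
    fg = v.data[fg_mask].astype(np.float64)
    if fg.size == 0:
        raise ValueError("volume has empty foreground")
    own = np.percentile(fg, lm.percentiles)
    if own[-1] <= own[0]:
        raise ValueError("degenerate (constant) foreground")
    own, idx = np.unique(own, return_index=True)
    scale = np.asarray(lm.standard_scale)[idx]
    mapped = np.interp(fg, own, scale)
    # extrapolate linearly past the end landmarks, then clip
    lo_slope = (scale[1] - scale[0]) / (own[1] - own[0]) if len(own) > 1 else 1.0
    hi_slope = (scale[-1] - scale[-2]) / (own[-1] - own[-2]) if len(own) > 1 else 1.0
    below = fg < own[0]
    above = fg > own[-1]
    mapped[below] = scale[0] + (fg[below] - own[0]) * lo_slope
    mapped[above] = scale[-1] + (fg[above] - own[-1]) * hi_slope
    mapped = np.clip(mapped, lm.floor, lm.ceiling)
    out = v.data.astype(np.float64).copy()
    out[fg_mask] = mapped
    return v.with_data(out)
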