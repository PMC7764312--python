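"""Whole-volume segmentation: patch planning with guaranteed coverage,
per-patch prediction, OR logical label fusion, and back-registration.

Fusion semantics: per voxel, the argmax label of every covering patch is
collected. If every covering patch claims background the voxel stays
background; any non-background claim beats background ("OR"); conflicting
non-background claims are resolved by the largest summed probability over
covering patches, ties broken toward the smallest label id. Voxels covered
by exactly one patch reduce to a naive concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_schema import LabelSchema, LabelVolume, Volume3D
from .preprocess import (HistogramLandmarks, RigidTransform, crop_labels,
                         identity_backend, pad_volume, register_to_template,
                         resample_to_grid, standardize_intensity)
from .training import Checkpoint

__all__ = [
    "PatchPlan",
    "plan_patches",
    "predict_patches",
    "fuse_or_logical",
    "to_native_space",
    "segment_volume",
    "PipelineConfig",
]

DEFAULT_PATCH = (96, 96, 96)
DEFAULT_OVERLAP = (12, 12, 12)
DEFAULT_N_PATCHES = 128
TEST_PAD = (24, 24, 24)


@dataclass
class PatchPlan:
    patch_size: tuple[int, int, int]
    origins: list[tuple[int, int, int]]
    volume_shape: tuple[int, int, int]
    mode: str = "grid"  # grid | random
    overlap: tuple[int, int, int] = (12, 12, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        self.patch_size = tuple(int(s) for s in self.patch_size)
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        self.origins = [tuple(int(o) for o in origin) for origin in self.origins]
        for origin in self.origins:
            for o, s, n in zip(origin, self.patch_size, self.volume_shape):
                if o < 0 or o + s > n:
                    raise ValueError(f"patch at {origin} exceeds volume "
                                     f"{self.volume_shape}")
        if not self._coverage_ok():
            raise ValueError("patch plan does not cover every voxel")

    def _coverage_ok(self) -> bool:
        return bool(np.all(self.coverage_count() > 0))

    def coverage_count(self) -> np.ndarray:
        count = np.zeros(self.volume_shape, dtype=np.int32)
        for origin in self.origins:
            sl = tuple(slice(o, o + s) for o, s in zip(origin, self.patch_size))
            count[sl] += 1
        return count

    def __len__(self) -> int:
        return len(self.origins)


def _grid_origins_1d(n: int, size: int, overlap: int) -> list[int]:
    stride = size - overlap
    if stride <= 0:
        raise ValueError(f"overlap {overlap} >= patch size {size}")
    origins = list(range(0, max(n - size, 0) + 1, stride))
    if origins[-1] + size < n:  # clamp the last patch to the boundary
        origins.append(n - size)
    return origins


def plan_patches(volume_shape: Sequence[int],
                 patch_size: Sequence[int] = DEFAULT_PATCH,
                 overlap: Sequence[int] = DEFAULT_OVERLAP,
                 mode: str = "grid",
                 n_patches: int = DEFAULT_N_PATCHES,
                 rng: np.random.Generator | None = None,
                 seed: int = 0) -> PatchPlan:
    """Build a covering patch plan.

    grid: regular tiling with stride = size - overlap, last patch clamped.
    random: ``n_patches`` uniform origins, then grid origins appended until
    every voxel is covered (coverage is a hard contract).
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    patch_size = tuple(int(s) for s in patch_size)
    overlap = tuple(int(o) for o in overlap)
    for n, s in zip(volume_shape, patch_size):
        if s > n:
            raise ValueError(f"patch {patch_size} larger than volume "
                             f"{volume_shape}")
    grid = [(i, j, k)
            for i in _grid_origins_1d(volume_shape[0], patch_size[0], overlap[0])
            for j in _grid_origins_1d(volume_shape[1], patch_size[1], overlap[1])
            for k in _grid_origins_1d(volume_shape[2], patch_size[2], overlap[2])]
    if mode == "grid":
        origins = grid
    elif mode == "random":
        rng = rng if rng is not None else np.random.default_rng(seed)
        origins = [tuple(int(rng.integers(0, n - s + 1))
                         for n, s in zip(volume_shape, patch_size))
                   for _ in range(n_patches)]
        covered = np.zeros(volume_shape, dtype=bool)
        for origin in origins:
            sl = tuple(slice(o, o + s) for o, s in zip(origin, patch_size))
            covered[sl] = True
        if not covered.all():
            for origin in grid:
                sl = tuple(slice(o, o + s) for o, s in zip(origin, patch_size))
                if not covered[sl].all():
                    origins.append(origin)
                    covered[sl] = True
            # grid tiles cover everything, so we are done
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PatchPlan(patch_size, origins, volume_shape, mode, overlap, seed)


def predict_patches(ckpt: Checkpoint, v: Volume3D, plan: PatchPlan,
                    net=None) -> list[np.ndarray]:
    """One (N, *patch) probability grid per plan origin; nothing outside the
    patch bounds is predicted (no extrapolation)."""
    if tuple(v.shape) != plan.volume_shape:
        raise ValueError(f"volume shape {v.shape} != plan shape "
                         f"{plan.volume_shape}")
    if net is None:
        net = ckpt.build()
    outputs = []
    for origin in plan.origins:
        sl = tuple(slice(o, o + s) for o, s in zip(origin, plan.patch_size))
        patch = np.asarray(v.data[sl], dtype=np.float32)
        outputs.append(net.predict_probs(patch))
    return outputs


def fuse_or_logical(patch_probs: Sequence[np.ndarray], plan: PatchPlan,
                    schema: LabelSchema,
                    spacing=(1.0, 1.0, 1.0), affine=None) -> LabelVolume:
    """Fuse per-patch probability grids into one label volume (see module doc)."""
    if len(patch_probs) != len(plan.origins):
        raise ValueError("one probability grid required per plan origin")
    shape = plan.volume_shape
    n_classes = patch_probs[0].shape[0] if patch_probs else schema.n_classes
    score = np.zeros((n_classes,) + shape, dtype=np.float32)
    nonbg = np.zeros(shape, dtype=bool)
    covered = np.zeros(shape, dtype=bool)
    for probs, origin in zip(patch_probs, plan.origins):
        if probs.shape != (n_classes,) + plan.patch_size:
            raise ValueError(f"probability grid shape {probs.shape} does not "
                             f"match (N, *patch)")
        sl = tuple(slice(o, o + s) for o, s in zip(origin, plan.patch_size))
        claim = probs.argmax(axis=0)
        claim_p = np.take_along_axis(probs, claim[None], axis=0)[0]
        gi, gj, gk = np.ogrid[[slice(0, s) for s in plan.patch_size]]
        score[(slice(None),) + sl][claim, gi, gj, gk] += claim_p
        nonbg[sl] |= claim != 0
        covered[sl] = True
    if not covered.all():
        raise ValueError("fusion input does not cover every voxel")
    labels = np.zeros(shape, dtype=np.int32)
    if n_classes > 1:
        fg_choice = score[1:].argmax(axis=0).astype(np.int32) + 1
        labels[nonbg] = fg_choice[nonbg]
    return LabelVolume(labels, schema, spacing, affine)


def to_native_space(lv: LabelVolume, t: RigidTransform,
                    native: Volume3D) -> LabelVolume:
    """Nearest-neighbor resample of template-space labels onto the native grid.

    ``t`` is the stored forward transform (native world -> template world);
    labels are pulled back through its inverse.
    """
    if t is None:
        raise ValueError("missing registration transform")
    template_vol = Volume3D(lv.data.astype(np.float64), lv.spacing, lv.affine)
    if t.is_identity() and lv.shape == native.shape \
            and np.allclose(lv.affine, native.affine):
        return LabelVolume(lv.data.copy(), lv.schema, native.spacing,
                           native.affine.copy())
    # labels live in template space; map them to native: native = t^-1(template)
    out = resample_to_grid(template_vol, native, t.inverse(), order=0)
    return LabelVolume(np.rint(out.data).astype(np.int32), lv.schema,
                       native.spacing, native.affine.copy())


@dataclass
class PipelineConfig:
    schema: LabelSchema
    pad: tuple[int, int, int] = TEST_PAD
    patch_size: tuple[int, int, int] = DEFAULT_PATCH
    overlap: tuple[int, int, int] = DEFAULT_OVERLAP
    mode: str = "grid"
    n_patches: int = DEFAULT_N_PATCHES
    seed: int = 0
    landmarks: HistogramLandmarks | None = None
    template: Volume3D | None = None
    registration_backend: object = field(default=identity_backend)


def segment_volume(ckpt: Checkpoint, raw: Volume3D,
                   cfg: PipelineConfig) -> LabelVolume:
    """register -> pad -> standardize -> plan -> predict -> fuse -> unpad ->
    back-register."""
    if ckpt.network.n_classes < cfg.schema.n_classes:
        raise ValueError(
            f"checkpoint outputs {ckpt.network.n_classes} classes but schema "
            f"has {cfg.schema.n_classes}")
    template = cfg.template if cfg.template is not None else raw
    registered, transform = register_to_template(raw, template,
                                                 cfg.registration_backend)
    if cfg.landmarks is not None:
        registered = standardize_intensity(registered, cfg.landmarks)
    padded = pad_volume(registered, cfg.pad)
    plan = plan_patches(padded.shape, cfg.patch_size, cfg.overlap,
                        mode=cfg.mode, n_patches=cfg.n_patches, seed=cfg.seed)
    net = ckpt.build()
    probs = predict_patches(ckpt, padded, plan, net=net)
    fused = fuse_or_logical(probs, plan, cfg.schema, padded.spacing,
                            padded.affine)
    cropped = crop_labels(fused, cfg.pad)
    template_labels = LabelVolume(cropped.data, cfg.schema,
                                  registered.spacing, registered.affine)
    return to_native_space(template_labels, transform, raw)
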