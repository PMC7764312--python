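"""Deterministic synthetic T1-like phantoms for end-to-end testing.

Generates nested-ellipsoid tissue compartments with per-tissue intensities,
additive Gaussian noise and a smooth multiplicative bias field, plus
systematically corrupted "auxiliary" label maps, paired test-retest scans
and multi-center scan sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_schema import LabelSchema, LabelVolume, SchemaEntry, Volume3D

__all__ = [
    "TissueSpec",
    "PhantomSpec",
    "DegradationSpec",
    "make_phantom",
    "degrade_labels",
    "make_paired_set",
    "make_multicenter_set",
    "default_phantom_spec",
    "varied_phantom_spec",
]


@dataclass(frozen=True)
class TissueSpec:
    """One painted ellipsoid: label id, center/semi-axes in voxels, intensity."""

    label: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    mean: float
    sd: float = 0.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    tissues: list[TissueSpec]
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    schema: LabelSchema | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise sd and bias amplitude must be non-negative")
        for t in self.tissues:
            if any(a <= 0 for a in t.semi_axes):
                raise ValueError(f"tissue {t.label}: semi-axes must be positive")
            for c, a, n in zip(t.center, t.semi_axes, self.shape):
                if c - a < 0 or c + a > n - 1:
                    raise ValueError(
                        f"tissue {t.label}: ellipsoid exceeds the grid "
                        f"(center {t.center}, semi-axes {t.semi_axes}, shape {self.shape})")
        if self.schema is None:
            self.schema = self._implied_schema()
        ids = set(self.schema.ids)
        for t in self.tissues:
            if t.label not in ids:
                raise ValueError(f"tissue label {t.label} not in schema")

    def _implied_schema(self) -> LabelSchema:
        max_id = max((t.label for t in self.tissues), default=0)
        entries = [SchemaEntry(0, "background")]
        entries += [SchemaEntry(i, f"structure_{i}") for i in range(1, max_id + 1)]
        return LabelSchema(entries)


@dataclass
class DegradationSpec:
    """Systematic label corruption emulating auto-generated auxiliary labels."""

    dilation_radius: dict[int, int] = field(default_factory=dict)  # label -> voxels (neg = erode)
    flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip probability must be in [0, 1]")


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float],
                    semi_axes: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _bias_field(shape: Sequence[int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """exp of a random 3rd-order polynomial in normalized [-1, 1] coordinates."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    poly = np.zeros(tuple(shape), dtype=np.float64)
    # all monomials x^i y^j z^k with 0 < i+j+k <= 3
    for i in range(4):
        for j in range(4 - i):
            for k in range(4 - i - j):
                c = rng.uniform(-amplitude, amplitude)
                if i + j + k == 0:
                    continue
                poly = poly + c * (x ** i) * (y ** j) * (z ** k)
    return np.exp(poly)


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelVolume]:
    """Render the painted-ellipsoid phantom; later tissues overwrite earlier ones."""
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int32)
    intensity = np.zeros(spec.shape, dtype=np.float64)
    for t in spec.tissues:
        mask = _ellipsoid_mask(spec.shape, t.center, t.semi_axes)
        labels[mask] = t.label
        intensity[mask] = t.mean
    # per-tissue texture, then global noise, then multiplicative bias
    for t in spec.tissues:
        if t.sd > 0:
            mask = labels == t.label
            intensity[mask] += rng.normal(0.0, t.sd, size=int(mask.sum()))
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.bias_amplitude > 0:
        intensity = intensity * _bias_field(spec.shape, spec.bias_amplitude, rng)
    vol = Volume3D(intensity, spec.spacing)
    lv = LabelVolume(labels, spec.schema, spec.spacing, vol.affine.copy())
    return vol, lv


_BALL_CACHE: dict[int, np.ndarray] = {}


def _ball(radius: int) -> np.ndarray:
    if radius not in _BALL_CACHE:
        r = radius
        g = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
        _BALL_CACHE[radius] = (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r ** 2
    return _BALL_CACHE[radius]


_FACE_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _shift(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift with edge replication (labels at the border keep themselves)."""
    out = arr
    for axis, off in enumerate(offset):
        if off:
            out = np.take(out, np.clip(np.arange(out.shape[axis]) - off, 0,
                                       out.shape[axis] - 1), axis=axis)
    return out


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-connected neighbor of a different label."""
    out = np.zeros(labels.shape, dtype=bool)
    for off in _FACE_SHIFTS:
        out |= _shift(labels, off) != labels
    return out


def degrade_labels(lv: LabelVolume, d: DegradationSpec) -> LabelVolume:
    """Dilate/erode per label then randomly flip boundary voxels to a neighbor label."""
    rng = np.random.default_rng(d.seed)
    out = lv.data.copy()
    for label in sorted(d.dilation_radius):
        radius = int(d.dilation_radius[label])
        if radius == 0:
            continue
        mask = out == label
        if not mask.any():
            continue
        if radius > 0:
            grown = ndimage.binary_dilation(mask, structure=_ball(radius))
            out[grown & ~mask] = label
        else:
            kept = ndimage.binary_erosion(mask, structure=_ball(-radius))
            out[mask & ~kept] = 0
    if d.flip_probability > 0:
        edge = boundary_mask(out)
        flip = edge & (rng.random(out.shape) < d.flip_probability)
        if flip.any():
            neighbors = np.stack([_shift(out, off) for off in _FACE_SHIFTS])
            pick = rng.integers(0, len(_FACE_SHIFTS), size=out.shape)
            chosen = np.take_along_axis(neighbors, pick[None], axis=0)[0]
            out[flip] = chosen[flip]
    return LabelVolume(out, lv.schema, lv.spacing, lv.affine.copy())


def _rigid_jitter(vol: Volume3D, angles_deg: np.ndarray,
                  shift_vox: np.ndarray) -> Volume3D:
    """Small rigid perturbation about the grid center (trilinear resampling)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
    center = (np.asarray(vol.shape) - 1) / 2.0
    # output voxel -> input voxel: x_in = R^T (x_out - c - t) + c
    matrix = rot.T
    offset = center - matrix @ (center + shift_vox)
    data = ndimage.affine_transform(vol.data, matrix, offset=offset,
                                    order=1, mode="constant", cval=0.0)
    return vol.with_data(data)


def make_paired_set(spec: PhantomSpec, n_pairs: int,
                    jitter_deg: float = 0.0, jitter_vox: float = 0.0,
                    ) -> list[tuple[Volume3D, Volume3D]]:
    """Test-retest pairs: shared anatomy, independent noise, small rigid jitter.

    With ``jitter_deg == jitter_vox == 0`` and zero noise the two scans of a
    pair are identical, so downstream CVs_avg is exactly 0.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    pairs = []
    base = np.random.default_rng(spec.seed)
    for i in range(n_pairs):
        seed_a = int(base.integers(0, 2 ** 31))
        seed_b = int(base.integers(0, 2 ** 31))
        spec_a = _reseeded(spec, seed_a)
        spec_b = _reseeded(spec, seed_b)
        vol_a, _ = make_phantom(spec_a)
        vol_b, _ = make_phantom(spec_b)
        if jitter_deg > 0 or jitter_vox > 0:
            jr = np.random.default_rng(seed_b ^ 0x5EED)
            angles = jr.uniform(-jitter_deg, jitter_deg, size=3)
            shift = jr.uniform(-jitter_vox, jitter_vox, size=3)
            vol_b = _rigid_jitter(vol_b, angles, shift)
        pairs.append((vol_a, vol_b))
    return pairs


def _reseeded(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return PhantomSpec(spec.shape, spec.tissues, spec.noise_sd,
                       spec.bias_amplitude, seed, spec.spacing, spec.schema)


def make_multicenter_set(spec: PhantomSpec, n_sites: int,
                         scales: Sequence[float] | None = None,
                         offsets: Sequence[float] | None = None,
                         noise_sds: Sequence[float] | None = None,
                         ) -> list[Volume3D]:
    """One subject rendered at n_sites under per-site intensity transforms."""
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    scales = list(scales) if scales is not None else [1.0] * n_sites
    offsets = list(offsets) if offsets is not None else [0.0] * n_sites
    noise_sds = list(noise_sds) if noise_sds is not None else [spec.noise_sd] * n_sites
    if not (len(scales) == len(offsets) == len(noise_sds) == n_sites):
        raise ValueError("per-site parameter lists must have length n_sites")
    clean = PhantomSpec(spec.shape, spec.tissues, 0.0, spec.bias_amplitude,
                        spec.seed, spec.spacing, spec.schema)
    vol, _ = make_phantom(clean)
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    for s, o, sd in zip(scales, offsets, noise_sds):
        data = vol.data * s + o
        if sd > 0:
            data = data + rng.normal(0.0, sd, size=vol.shape)
        out.append(vol.with_data(data))
    return out


def default_phantom_spec(shape: tuple[int, int, int] = (64, 64, 64),
                         seed: int = 0,
                         noise_sd: float = 2.0,
                         bias_amplitude: float = 0.1) -> PhantomSpec:
    """Desk-scale phantom: background + 4 bilateral structure pairs.

    A large head ellipsoid (label 1/2 split as two hemispheres) would be
    anatomically cute but hard to reason about; instead the default places
    a big central compartment and bilateral small blobs with distinct mean
    intensities so that each label is learnable from local patches.
    """
    n = np.asarray(shape, dtype=float)
    c = (n - 1) / 2.0
    r = n / 2.0
    lx = c[0] - r[0] * 0.42
    rx = c[0] + r[0] * 0.42
    tissues = [
        # two large hemispheric compartments (pair 1)
        TissueSpec(1, (lx, c[1], c[2]), tuple(r * (0.42, 0.75, 0.75)), 90.0, 1.0),
        TissueSpec(2, (rx, c[1], c[2]), tuple(r * (0.42, 0.75, 0.75)), 110.0, 1.0),
        # mid-size deep structures (pair 2)
        TissueSpec(3, (lx, c[1] - r[1] * 0.3, c[2]), tuple(r * (0.26, 0.36, 0.36)), 140.0, 1.0),
        TissueSpec(4, (rx, c[1] - r[1] * 0.3, c[2]), tuple(r * (0.26, 0.36, 0.36)), 160.0, 1.0),
        # small bright blobs (pair 3)
        TissueSpec(5, (lx, c[1] + r[1] * 0.32, c[2] - r[2] * 0.24),
                   tuple(r * (0.22, 0.24, 0.24)), 190.0, 1.0),
        TissueSpec(6, (rx, c[1] + r[1] * 0.32, c[2] - r[2] * 0.24),
                   tuple(r * (0.22, 0.24, 0.24)), 210.0, 1.0),
        # small dark blobs (pair 4)
        TissueSpec(7, (lx, c[1] + r[1] * 0.3, c[2] + r[2] * 0.3),
                   tuple(r * (0.2, 0.22, 0.22)), 40.0, 1.0),
        TissueSpec(8, (rx, c[1] + r[1] * 0.3, c[2] + r[2] * 0.3),
                   tuple(r * (0.2, 0.22, 0.22)), 60.0, 1.0),
    ]
    entries = [SchemaEntry(0, "background")]
    pair_names = ["compartment", "deep", "bright_blob", "dark_blob"]
    i = 1
    for name in pair_names:
        entries.append(SchemaEntry(i, f"{name}_left", "left"))
        entries.append(SchemaEntry(i + 1, f"{name}_right", "right"))
        i += 2
    schema = LabelSchema(entries)
    return PhantomSpec(tuple(shape), tissues, noise_sd, bias_amplitude, seed,
                       schema=schema)


def varied_phantom_spec(shape: tuple[int, int, int] = (64, 64, 64),
                        seed: int = 0,
                        noise_sd: float = 2.0,
                        bias_amplitude: float = 0.1,
                        center_jitter: float = 0.04,
                        axis_jitter: float = 0.10) -> PhantomSpec:
    """Desk phantom with per-subject anatomical variation.

    Ellipsoid centers and semi-axes of :func:`default_phantom_spec` are
    jittered deterministically from the seed (fractions of the grid edge /
    relative semi-axis change), giving distinct but same-schema subjects for
    train/test splits.
    """
    base = default_phantom_spec(shape, seed=seed, noise_sd=noise_sd,
                                bias_amplitude=bias_amplitude)
    rng = np.random.default_rng(seed)
    n = np.asarray(shape, dtype=float)
    tissues = []
    for t in base.tissues:
        center = np.asarray(t.center) + rng.uniform(-center_jitter,
                                                    center_jitter, 3) * n
        semi = np.asarray(t.semi_axes) * rng.uniform(1 - axis_jitter,
                                                     1 + axis_jitter, 3)
        # clamp inside the grid
        semi = np.minimum(semi, np.minimum(center, n - 1 - center) - 0.5)
        tissues.append(TissueSpec(t.label, tuple(center), tuple(semi),
                                  t.mean, t.sd))
    return PhantomSpec(tuple(shape), tissues, noise_sd, bias_amplitude, seed,
                       schema=base.schema)
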