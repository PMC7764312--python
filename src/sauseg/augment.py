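"""Training-time stochastic transforms: Gaussian noise, multiplicative bias
field, affine (scale + rotation only) and elastic deformation.

Default parameter ranges: noise sd in [0, 0.2] (on standardized ~[0, 1]
intensities), bias polynomial coefficients in [-0.5, 0.5], scale in
[0.9, 1.1], rotation in [-10, 10] degrees, a 7x7x7 elastic control grid.
Geometric transforms apply one displacement field to the image (trilinear)
and its labels (nearest-neighbor), so image/label pairs never drift apart.
Composition order is fixed: noise -> bias -> affine -> elastic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .io_schema import LabelVolume, Volume3D

__all__ = [
    "AugmentConfig",
    "gaussian_noise",
    "bias_field",
    "random_affine",
    "elastic",
    "compose",
    "sample_parameters",
]


@dataclass
class AugmentConfig:
    noise_sd_range: tuple[float, float] = (0.0, 0.2)
    bias_coeff_range: tuple[float, float] = (-0.5, 0.5)
    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    elastic_control_points: int = 7
    elastic_max_displacement: float = 2.0  # voxels
    p_noise: float = 0.5
    p_bias: float = 0.5
    p_affine: float = 0.5
    p_elastic: float = 0.5

    def __post_init__(self) -> None:
        for name in ("noise_sd_range", "bias_coeff_range", "scale_range",
                     "rotation_range_deg"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is not well-ordered: ({lo}, {hi})")
        if self.elastic_control_points < 2:
            raise ValueError("need at least 2 elastic control points per axis")
        for name in ("p_noise", "p_bias", "p_affine", "p_elastic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


def gaussian_noise(v: Volume3D, sd: float, rng: np.random.Generator) -> Volume3D:
    """Independent zero-mean Gaussian noise per voxel."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return v.with_data(v.data.copy())
    return v.with_data(v.data + rng.normal(0.0, sd, size=v.shape))


def _polynomial_field(shape, coefficients: np.ndarray) -> np.ndarray:
    """3rd-order polynomial over normalized [-1, 1] coordinates; exp'd."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    poly = np.zeros(tuple(shape))
    it = iter(coefficients)
    for i in range(4):
        for j in range(4 - i):
            for k in range(4 - i - j):
                if i + j + k == 0:
                    continue
                poly = poly + next(it) * (x ** i) * (y ** j) * (z ** k)
    return np.exp(poly)


N_BIAS_COEFFICIENTS = sum(1 for i in range(4) for j in range(4 - i)
                          for k in range(4 - i - j) if i + j + k > 0)


def bias_field(v: Volume3D, coefficients: np.ndarray | None,
               rng: np.random.Generator,
               coeff_range: tuple[float, float] = (-0.5, 0.5)) -> Volume3D:
    """Multiply by exp(P(x)), P a 3rd-order polynomial; field always > 0."""
    if coefficients is None:
        coefficients = rng.uniform(*coeff_range, size=N_BIAS_COEFFICIENTS)
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size != N_BIAS_COEFFICIENTS:
        raise ValueError(f"need {N_BIAS_COEFFICIENTS} coefficients, "
                         f"got {coefficients.size}")
    field = _polynomial_field(v.shape, coefficients)
    return v.with_data(v.data * field)


def _affine_voxel_map(shape, scale: float, angles_deg) -> tuple[np.ndarray, np.ndarray]:
    """Output-to-input voxel map for rotation+scale about the grid center."""
    rot = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
    fwd = rot * scale
    inv = np.linalg.inv(fwd)
    center = (np.asarray(shape) - 1) / 2.0
    offset = center - inv @ center
    return inv, offset


def random_affine(v: Volume3D, lv: LabelVolume | None, scale: float,
                  angles_deg, rng: np.random.Generator | None = None,
                  ) -> tuple[Volume3D, LabelVolume | None]:
    """Isotropic scale + rotation about the center; no shear, no translation.

    The image is resampled trilinearly, labels nearest-neighbor with the
    SAME transform.
    """
    angles_deg = tuple(float(a) for a in np.atleast_1d(angles_deg)) \
        if np.ndim(angles_deg) else (float(angles_deg),) * 3
    if len(angles_deg) == 1:
        angles_deg = angles_deg * 3
    if scale == 1.0 and all(a == 0.0 for a in angles_deg):
        out_lv = None if lv is None else LabelVolume(
            lv.data.copy(), lv.schema, lv.spacing, lv.affine.copy())
        return v.with_data(v.data.copy()), out_lv
    matrix, offset = _affine_voxel_map(v.shape, scale, angles_deg)
    data = ndimage.affine_transform(v.data.astype(np.float64), matrix,
                                    offset=offset, order=1, mode="constant")
    out_lv = None
    if lv is not None:
        ldata = ndimage.affine_transform(lv.data, matrix, offset=offset,
                                         order=0, mode="constant", cval=0)
        out_lv = LabelVolume(ldata.astype(lv.data.dtype), lv.schema,
                             lv.spacing, lv.affine.copy())
    return v.with_data(data), out_lv


def _elastic_displacement(shape, control_points: int, max_displacement: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Smooth (3, D, H, W) displacement field from a random control grid."""
    ctrl = rng.uniform(-max_displacement, max_displacement,
                       size=(3, control_points, control_points, control_points))
    field = np.empty((3,) + tuple(shape))
    zoom = [n / control_points for n in shape]
    for axis in range(3):
        field[axis] = ndimage.zoom(ctrl[axis], zoom, order=3, mode="nearest",
                                   grid_mode=True)
    return field


def elastic(v: Volume3D, lv: LabelVolume | None, control_points: int,
            max_displacement: float, rng: np.random.Generator,
            ) -> tuple[Volume3D, LabelVolume | None]:
    """Elastic deformation from a random control-point grid (one shared field)."""
    if max_displacement == 0:
        out_lv = None if lv is None else LabelVolume(
            lv.data.copy(), lv.schema, lv.spacing, lv.affine.copy())
        return v.with_data(v.data.copy()), out_lv
    field = _elastic_displacement(v.shape, control_points, max_displacement, rng)
    base = np.meshgrid(*[np.arange(n, dtype=float) for n in v.shape],
                       indexing="ij")
    coords = [b + f for b, f in zip(base, field)]
    data = ndimage.map_coordinates(v.data.astype(np.float64), coords, order=1,
                                   mode="constant")
    out_lv = None
    if lv is not None:
        ldata = ndimage.map_coordinates(lv.data, coords, order=0,
                                        mode="constant", cval=0)
        out_lv = LabelVolume(ldata.astype(lv.data.dtype), lv.schema,
                             lv.spacing, lv.affine.copy())
    return v.with_data(data), out_lv


def sample_parameters(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of per-call augmentation parameters."""
    return {
        "apply_noise": rng.random() < cfg.p_noise,
        "apply_bias": rng.random() < cfg.p_bias,
        "apply_affine": rng.random() < cfg.p_affine,
        "apply_elastic": rng.random() < cfg.p_elastic,
        "noise_sd": rng.uniform(*cfg.noise_sd_range),
        "bias_coefficients": rng.uniform(*cfg.bias_coeff_range,
                                         size=N_BIAS_COEFFICIENTS),
        "scale": rng.uniform(*cfg.scale_range),
        "angles_deg": rng.uniform(*cfg.rotation_range_deg, size=3),
        "elastic_max_displacement": cfg.elastic_max_displacement,
    }


def compose(cfg: AugmentConfig, rng: np.random.Generator,
            ) -> Callable[[Volume3D, LabelVolume | None],
                          tuple[Volume3D, LabelVolume | None]]:
    """Return a transform applying noise -> bias -> affine -> elastic.

    Parameters are re-sampled uniformly in their configured ranges on every
    call (per patch); the rng is the single source of randomness.
    """

    def transform(v: Volume3D, lv: LabelVolume | None = None):
        params = sample_parameters(cfg, rng)
        if params["apply_noise"]:
            v = gaussian_noise(v, params["noise_sd"], rng)
        if params["apply_bias"]:
            v = bias_field(v, params["bias_coefficients"], rng)
        if params["apply_affine"]:
            v, lv = random_affine(v, lv, params["scale"], params["angles_deg"])
        if params["apply_elastic"]:
            v, lv = elastic(v, lv, cfg.elastic_control_points,
                            params["elastic_max_displacement"], rng)
        return v, lv

    return transform
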