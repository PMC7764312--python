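"""Core domain types, NIfTI I/O, label schemas and run configuration.

All other modules build on the three value types defined here:
:class:`Volume3D` (scalar intensity grid + geometry), :class:`LabelSchema`
(ordered id/name/laterality table with contiguous ids starting at 0) and
:class:`LabelVolume` (integer grid governed by a schema).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Volume3D",
    "LabelVolume",
    "LabelSchema",
    "SchemaEntry",
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "default_schema",
    "get_logger",
]

log = logging.getLogger("sauseg")


def get_logger(name: str = "sauseg", level: int = logging.INFO,
               logfile: str | Path | None = None) -> logging.Logger:
    """Return the package logger, configured for stderr (and optionally a file)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    logger.setLevel(level)
    return logger


# ---------------------------------------------------------------------------
# Volume3D


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with voxel spacing (mm) and grid-to-world affine.

    Voxel indices are 0-based; world coordinates follow the NIfTI affine
    convention ``world = affine @ (i, j, k, 1)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D data must have 3 axes, got {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine upper-left 3x3 must be non-singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same geometry, new voxel data (must keep the grid shape)."""
        if data.shape != self.data.shape:
            raise ValueError("with_data must preserve shape")
        return Volume3D(data, self.spacing, self.affine.copy())

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        return (self.affine @ np.array([*ijk, 1.0]))[:3]


# ---------------------------------------------------------------------------
# LabelSchema


@dataclass(frozen=True)
class SchemaEntry:
    id: int
    name: str
    laterality: str = "none"  # left | right | none

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right", "none"):
            raise ValueError(f"bad laterality {self.laterality!r}")


@dataclass
class LabelSchema:
    """Ordered list of (id, name, laterality) with contiguous ids from 0."""

    entries: list[SchemaEntry]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if ids != list(range(len(ids))):
            raise ValueError("schema ids must be unique and contiguous from 0")
        if not ids:
            raise ValueError("schema must not be empty")
        if self.entries[0].name != "background":
            raise ValueError("id 0 must be named 'background'")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[int]:
        return [e.id for e in self.entries]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    def foreground_ids(self) -> list[int]:
        return [e.id for e in self.entries if e.id != 0]

    def subset(self, ids: Sequence[int]) -> list[SchemaEntry]:
        """Evaluation-subset filter (not a new schema)."""
        wanted = set(ids)
        return [e for e in self.entries if e.id in wanted]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("id\tname\tlaterality\n")
            for e in self.entries:
                fh.write(f"{e.id}\t{e.name}\t{e.laterality}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelSchema":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                parts = dict(zip(header, line.rstrip("\n").split("\t")))
                entries.append(SchemaEntry(int(parts["id"]), parts["name"],
                                           parts.get("laterality", "none")))
        return cls(entries)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = [{"id": e.id, "name": e.name, "laterality": e.laterality}
                   for e in self.entries]
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSchema":
        payload = json.loads(Path(path).read_text())
        return cls([SchemaEntry(d["id"], d["name"], d.get("laterality", "none"))
                    for d in payload])


_BILATERAL = [
    "cerebral_white_matter",
    "lateral_ventricle",
    "caudate",
    "accumbens",
    "putamen",
    "amygdala",
    "hippocampus",
    "pallidum",
    "thalamus",
]


def default_schema() -> LabelSchema:
    """The reference 34-class whole-brain schema.

    Id 0 is background; ids 1-18 are the nine bilateral structures
    (left/right pairs); ids 19-33 are named placeholders and are intended
    to be overridden by a user-supplied schema when the full structure list
    is known.
    """
    entries = [SchemaEntry(0, "background", "none")]
    next_id = 1
    for name in _BILATERAL:
        entries.append(SchemaEntry(next_id, f"{name}_left", "left"))
        entries.append(SchemaEntry(next_id + 1, f"{name}_right", "right"))
        next_id += 2
    while next_id < 34:
        entries.append(SchemaEntry(next_id, f"structure_{next_id}", "none"))
        next_id += 1
    return LabelSchema(entries)


# ---------------------------------------------------------------------------
# LabelVolume


@dataclass
class LabelVolume:
    """Integer label grid aligned to a Volume3D and governed by a LabelSchema."""

    data: np.ndarray
    schema: LabelSchema
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label data must be integer-typed, got {self.data.dtype}")
        if self.data.ndim != 3:
            raise ValueError("label data must have 3 axes")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.data)
        known = set(self.schema.ids)
        unknown = [int(v) for v in present if int(v) not in known]
        if unknown:
            raise ValueError(f"labels {unknown} not in schema (max id {max(known)})")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == label_id

    def present_ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.data)]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _squeeze_to_3d(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3:
        return arr
    non_singleton = [s for s in arr.shape if s > 1]
    if len(non_singleton) > 3:
        raise ValueError(f"{path}: {arr.ndim}D image with >3 non-singleton axes")
    squeezed = np.squeeze(arr)
    if squeezed.ndim < 3:  # keep degenerate grids 3D
        squeezed = squeezed.reshape(squeezed.shape + (1,) * (3 - squeezed.ndim))
    return squeezed


def read_volume(path: str | Path) -> Volume3D:
    """Load a NIfTI-1/2 file as a Volume3D, intensities unmodified."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    arr = _squeeze_to_3d(arr, path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(arr, spacing, np.asarray(img.affine, dtype=float))


def write_volume(v: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return path.with_name(name + ".labels.tsv")


def write_labels(lv: LabelVolume, path: str | Path) -> Path:
    """Write an integer NIfTI plus a TSV schema sidecar; exact round-trip."""
    path = Path(path)
    if not np.issubdtype(lv.data.dtype, np.integer):
        raise TypeError("label volume must be integer-typed")
    img = nib.Nifti1Image(np.asarray(lv.data, dtype=np.int32), lv.affine)
    img.header.set_zooms(lv.spacing)
    nib.save(img, str(path))
    lv.schema.to_tsv(_sidecar_path(path))
    return path


def read_labels(path: str | Path, schema: LabelSchema | None = None) -> LabelVolume:
    """Load labels; schema from the TSV sidecar unless given explicitly."""
    path = Path(path)
    if schema is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"no schema given and no sidecar at {sidecar}")
        schema = LabelSchema.from_tsv(sidecar)
    img = nib.load(str(path))
    arr = _squeeze_to_3d(np.asarray(img.dataobj), path)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise TypeError(f"{path}: non-integer label data")
        arr = rounded.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(arr, schema, spacing, np.asarray(img.affine, dtype=float))


# ---------------------------------------------------------------------------
# RunConfig


@dataclass
class RunConfig:
    """Plumbing for reproducible runs: seed, paths, logging level, stage knobs."""

    seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(payload.get("seed", 0)),
            log_level=str(payload.get("log_level", "INFO")),
            paths=dict(payload.get("paths", {})),
            stages=dict(payload.get("stages", {})),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({
            "seed": self.seed, "log_level": self.log_level,
            "paths": self.paths, "stages": self.stages,
        }))
        return path

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
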