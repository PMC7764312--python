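"""Evaluation statistics: Dice overlap, average symmetric surface distance
(ASSD), structure volumes in cc, and the intra-session / total coefficients
of variation used for test-retest and multi-center reliability.

Conventions (documented because they pin the numbers down): boundaries are
6-connected — a mask voxel with at least one face-adjacent non-mask
neighbor — and ASSD distances are measured between boundary-voxel centers
in mm. Dice of two empty masks is 1; ASSD of an empty mask is an error.
CV formulas use the population (divide-by-n) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_schema import LabelVolume

__all__ = [
    "StructureMask",
    "PairedVolumes",
    "ScanSeries",
    "dice",
    "boundary",
    "assd",
    "volume_cc",
    "cv_intra_session",
    "cv_total",
    "evaluate_report",
]


@dataclass
class StructureMask:
    """Binary grid for a single label id, with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @classmethod
    def from_labels(cls, lv: LabelVolume, label_id: int) -> "StructureMask":
        return cls(lv.data == label_id, lv.spacing)

    @property
    def count(self) -> int:
        return int(self.data.sum())


def _check_same_grid(a: StructureMask, b: StructureMask) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"grid mismatch: {a.data.shape} vs {b.data.shape}")
    if a.spacing != b.spacing:
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def dice(a: StructureMask, b: StructureMask) -> float:
    """2|A ∩ B| / (|A| + |B|); 1.0 when both masks are empty."""
    _check_same_grid(a, b)
    total = a.count + b.count
    if total == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / total


def boundary(m: StructureMask) -> np.ndarray:
    """(K, 3) voxel indices of mask voxels with a 6-connected outside neighbor."""
    if m.count == 0:
        raise ValueError("boundary of an empty mask is undefined")
    mask = m.data
    interior = np.ones_like(mask)
    for axis in range(3):
        for direction in (1, -1):
            shifted = np.roll(mask, direction, axis=axis)
            edge_idx = 0 if direction == 1 else -1
            sl = [slice(None)] * 3
            sl[axis] = edge_idx
            shifted[tuple(sl)] = False  # outside the grid counts as non-mask
            interior &= shifted
    edge = mask & ~interior
    return np.argwhere(edge)


def assd(a: StructureMask, b: StructureMask) -> float:
    """Average symmetric surface distance in mm between boundary voxel centers."""
    _check_same_grid(a, b)
    if a.count == 0 or b.count == 0:
        raise ValueError("ASSD is undefined for an empty mask")
    spacing = np.asarray(a.spacing)
    pa = boundary(a) * spacing
    pb = boundary(b) * spacing
    tree_a = cKDTree(pa)
    tree_b = cKDTree(pb)
    d_ab, _ = tree_b.query(pa)
    d_ba, _ = tree_a.query(pb)
    return float((d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb)))


def volume_cc(m: StructureMask) -> float:
    """Voxel count times voxel volume, in cc (1 cc = 1000 mm^3)."""
    return m.count * float(np.prod(m.spacing)) / 1000.0


# ---------------------------------------------------------------------------
# reliability


@dataclass
class PairedVolumes:
    """Per-structure volume estimates (cc) for the 2 sessions of n pairs."""

    pairs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.pairs = [(float(x1), float(x2)) for x1, x2 in self.pairs]
        if not self.pairs:
            raise ValueError("need at least one pair")


@dataclass
class ScanSeries:
    """Per-structure volume estimates (cc) over n >= 2 scans of one subject."""

    values: list[float]

    def __post_init__(self) -> None:
        self.values = [float(x) for x in self.values]
        if len(self.values) < 2:
            raise ValueError("need at least two scans")


def cv_intra_session(pairs: PairedVolumes) -> float:
    """Mean over pairs of (population sd of the 2 sessions / pair mean), in %."""
    ratios = []
    for x1, x2 in pairs.pairs:
        mu = (x1 + x2) / 2.0
        if mu <= 0:
            raise ValueError("pair mean must be positive")
        sigma = np.sqrt(((x1 - mu) ** 2 + (x2 - mu) ** 2) / 2.0)
        ratios.append(sigma / mu)
    return float(np.mean(ratios) * 100.0)


def cv_total(series: ScanSeries) -> float:
    """Population sd over n scans divided by the mean, in %."""
    x = np.asarray(series.values)
    mu = x.mean()
    if mu <= 0:
        raise ValueError("series mean must be positive")
    sigma = np.sqrt(((x - mu) ** 2).mean())
    return float(sigma / mu * 100.0)


# ---------------------------------------------------------------------------
# reports


def evaluate_report(pred: LabelVolume, truth: LabelVolume,
                    label_ids: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-structure Dice/ASSD/volume table plus a mean ± sd summary row.

    Structures absent from both volumes get Dice 1 and no ASSD; absent from
    exactly one get Dice 0, no ASSD, and a flag.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    schema = truth.schema
    if label_ids is None:
        label_ids = schema.foreground_ids()
    rows = []
    for lid in label_ids:
        name = schema.entries[lid].name if lid < len(schema.entries) else str(lid)
        mp = StructureMask.from_labels(pred, lid)
        mt = StructureMask.from_labels(truth, lid)
        d = dice(mp, mt)
        if mp.count and mt.count:
            a = assd(mp, mt)
            flag = ""
        else:
            a = np.nan
            flag = "" if (mp.count == 0 and mt.count == 0) else "absent_in_one"
        rows.append({
            "label": lid, "name": name, "dice": d, "assd_mm": a,
            "volume_pred_cc": volume_cc(mp), "volume_truth_cc": volume_cc(mt),
            "flag": flag,
        })
    table = pd.DataFrame(rows)
    summary = {
        "label": -1, "name": "mean±sd",
        "dice": table["dice"].mean(), "assd_mm": table["assd_mm"].mean(),
        "volume_pred_cc": table["volume_pred_cc"].mean(),
        "volume_truth_cc": table["volume_truth_cc"].mean(),
        "flag": (f"dice_sd={table['dice'].std(ddof=0):.4f};"
                 f"assd_sd={table['assd_mm'].std(ddof=0):.4f}"),
    }
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
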