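"""Segmentation-quality metrics: DSC, NSD (surface Dice), HD95.

Boundary voxels are mask voxels with at least one six-connected
background neighbor (voxels on the grid border count as boundary).
Surface-to-surface distances are voxel-center Euclidean distances
computed with the exact distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io_volumes import LabelMask

__all__ = ["SegMetrics", "dice", "hd95", "nsd", "boundary", "evaluate"]


@dataclass
class SegMetrics:
    dsc: float
    nsd: float
    hd95_mm: float
    tolerance_mm: float

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "nsd": self.nsd,
                "hd95_mm": self.hd95_mm, "tolerance_mm": self.tolerance_mm}


def _check_grids(a: LabelMask, b: LabelMask) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError("masks are on different grids")
    if not np.allclose(a.spacing, b.spacing, atol=1e-3):
        raise ValueError("masks have different spacing")


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); both empty -> 1."""
    _check_grids(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.sum(a.data & b.data))
    return 2.0 * inter / (na + nb)


def boundary(mask: LabelMask) -> np.ndarray:
    """Mask voxels with a six-connected background neighbor (incl. grid border)."""
    struct = ndi.generate_binary_structure(3, 1)
    m = mask.bool
    eroded = ndi.binary_erosion(m, struct, border_value=0)
    return m & ~eroded


def _surface_distances(a: LabelMask, b: LabelMask) -> tuple[np.ndarray, np.ndarray]:
    """(distances from A-boundary to B-boundary, and vice versa), in mm."""
    sa, sb = boundary(a), boundary(b)
    spacing = tuple(a.spacing)
    dt_b = ndi.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndi.distance_transform_edt(~sa, sampling=spacing)
    return dt_b[sa], dt_a[sb]


def hd95(a: LabelMask, b: LabelMask, spacing=None) -> float:
    """95th percentile of the pooled symmetric surface distances (mm)."""
    _check_grids(a, b)
    if a.count() == 0 or b.count() == 0:
        raise ValueError("HD95 undefined for an empty mask")
    d_ab, d_ba = _surface_distances(a, b)
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, 95))  # linear interpolation


def nsd(a: LabelMask, b: LabelMask, spacing=None, tolerance_mm: float = 2.0) -> float:
    """Normalized surface distance (surface Dice at tolerance tau).

    Fraction of pooled boundary voxels lying within tau of the other
    mask's boundary: (|S_A within tau| + |S_B within tau|) / (|S_A| + |S_B|).
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance must be positive")
    _check_grids(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    d_ab, d_ba = _surface_distances(a, b)
    hits = int((d_ab <= tolerance_mm).sum()) + int((d_ba <= tolerance_mm).sum())
    return hits / (len(d_ab) + len(d_ba))


def evaluate(pred: LabelMask, truth: LabelMask, tolerance_mm: float = 2.0) -> SegMetrics:
    """All three metrics for one predicted/reference mask pair."""
    return SegMetrics(
        dsc=dice(pred, truth),
        nsd=nsd(pred, truth, tolerance_mm=tolerance_mm),
        hd95_mm=hd95(pred, truth),
        tolerance_mm=tolerance_mm,
    )
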