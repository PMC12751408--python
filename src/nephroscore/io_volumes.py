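"""Volumes and masks on a shared physical grid.

All scoring geometry in this package operates on two containers:

* :class:`VoxelVolume` — a 3D scalar field (CT attenuation in Hounsfield
  units, or a normalized intensity) with voxel spacing and origin in mm.
* :class:`LabelMask` — a binary field on the same lattice (kidney, tumor
  or sinus).

Axis convention is fixed on load: array axis 0 = x (left–right), axis 1 =
y (anterior–posterior), axis 2 = z (inferior→superior).  NIfTI inputs are
reoriented to the closest RAS-canonical orientation so that "axial plane"
and "craniocaudal axis" are well defined for the polar-line logic.

Physical coordinates use voxel centers: position = origin + index * spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "LabelMask",
    "SegmentationCase",
    "Finding",
    "read_volume",
    "read_mask",
    "read_label_map",
    "write_volume",
    "write_mask",
    "resample",
    "median_spacing",
    "window_normalize",
    "validate_case",
    "resolve_overlap",
]

#: grid spacings closer than this (mm) are considered identical
SPACING_ATOL_MM = 1e-3


def _check_grid_fields(data: np.ndarray, spacing, origin) -> tuple:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must be length-3 triples")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing}")
    return data, spacing, origin


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical spacing (mm/voxel) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data, self.spacing, self.origin = _check_grid_fields(
            self.data, self.spacing, self.origin
        )
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def same_grid(self, other: "VoxelVolume | LabelMask") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.spacing, other.spacing, atol=SPACING_ATOL_MM
        )


@dataclass
class LabelMask:
    """A binary 3D mask sharing the lattice of its paired :class:`VoxelVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data, self.spacing, self.origin = _check_grid_fields(
            self.data, self.spacing, self.origin
        )
        if data.dtype == bool:
            data = data.astype(np.uint8)
        else:
            vals = np.unique(data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"mask values must be binary (0/1); found {vals[:10]}"
                )
            data = data.astype(np.uint8)
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def bool(self) -> np.ndarray:
        return self.data.astype(np.bool_)

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return float(self.count() * np.prod(self.spacing))

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def same_grid(self, other: "VoxelVolume | LabelMask") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.spacing, other.spacing, atol=SPACING_ATOL_MM
        )


@dataclass
class SegmentationCase:
    """One scoring unit: a CT volume plus co-registered kidney and tumor masks."""

    image: VoxelVolume
    kidney: LabelMask
    tumor: LabelMask
    case_id: str = "case"


class Finding(NamedTuple):
    """A machine-readable validation finding (non-fatal)."""

    code: str
    message: str


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> VoxelVolume:
    """Read a NIfTI scalar volume, reoriented to RAS-canonical axes.

    Intensities are returned as stored (after the header's scale slope /
    intercept, which nibabel applies); no further rescaling is performed.
    """
    img = nib.load(str(path))
    if img.ndim == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if img.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D scalar volume, got shape {img.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: non-positive voxel spacing in header pixdim: {zooms}"
        )
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    data = np.asarray(img.get_fdata())
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelVolume(data, tuple(float(z) for z in zooms), origin)


def read_mask(path, label: int | None = None) -> LabelMask:
    """Read a binary mask; if ``label`` is given, extract that id from a label map."""
    vol = read_volume(path)
    data = vol.data
    if label is not None:
        data = (np.rint(data) == label)
    return LabelMask(np.rint(data).astype(np.uint8) if label is None else data,
                     vol.spacing, vol.origin)


def read_label_map(path, kidney_label: int = 1, tumor_label: int = 2
                   ) -> tuple[LabelMask, LabelMask]:
    """Split one integer label map into kidney and tumor masks (KiTS convention)."""
    vol = read_volume(path)
    lab = np.rint(vol.data).astype(np.int32)
    kidney = LabelMask(lab == kidney_label, vol.spacing, vol.origin)
    tumor = LabelMask(lab == tumor_label, vol.spacing, vol.origin)
    return kidney, tumor


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: VoxelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data, _affine(vol.spacing, vol.origin)), str(path))


def write_mask(mask: LabelMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.data, _affine(mask.spacing, mask.origin)), str(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample(obj: VoxelVolume | LabelMask,
             target_spacing: Sequence[float],
             kind: str | None = None) -> VoxelVolume | LabelMask:
    """Resample to a new isotropic/anisotropic spacing.

    Images use trilinear interpolation, labels nearest-neighbor, so a
    binary mask stays binary.  ``kind`` defaults to the type of ``obj``.
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"non-positive target spacing {target}")
    if kind is None:
        kind = "label" if isinstance(obj, LabelMask) else "image"
    if kind not in ("image", "label"):
        raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")
    if kind == "label" and not np.issubdtype(np.asarray(obj.data).dtype, np.integer):
        if not np.allclose(obj.data, np.rint(obj.data)):
            raise ValueError("kind='label' requires integer-valued data")

    if np.allclose(obj.spacing, target, atol=1e-12):
        return replace(obj, data=obj.data.copy())

    factors = [s / t for s, t in zip(obj.spacing, target)]
    order = 1 if kind == "image" else 0
    out = ndi.zoom(np.asarray(obj.data, dtype=float if kind == "image" else obj.data.dtype),
                   factors, order=order, mode="grid-constant", grid_mode=True)
    cls = type(obj)
    return cls(out, target, obj.origin)


def median_spacing(spacings: Sequence[Sequence[float]]) -> tuple[float, float, float]:
    """Component-wise median voxel size over a cohort (resampling target)."""
    arr = np.asarray(list(spacings), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected a sequence of (sx, sy, sz) triples")
    return tuple(float(v) for v in np.median(arr, axis=0))


def window_normalize(vol: VoxelVolume, width: float = 400.0,
                     level: float = 30.0) -> VoxelVolume:
    """Clip to a CT window then Z-score the clipped intensities.

    Defaults correspond to a soft-tissue window of 400 HU width at level
    30 HU, i.e. clip bounds [-170, 230] HU.  The output has mean 0 and
    unit standard deviation over all voxels.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    lo, hi = level - width / 2.0, level + width / 2.0
    clipped = np.clip(vol.data.astype(float), lo, hi)
    sd = float(clipped.std())
    if sd < 1e-12:
        raise ValueError("zero variance after windowing; cannot Z-score")
    out = (clipped - float(clipped.mean())) / sd
    return VoxelVolume(out, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Case validation
# ---------------------------------------------------------------------------

def validate_case(case: SegmentationCase) -> list[Finding]:
    """Check grid consistency and mask sanity; returns findings, raises nothing."""
    findings: list[Finding] = []
    for name, mask in (("kidney", case.kidney), ("tumor", case.tumor)):
        if case.image.data.shape != mask.data.shape:
            findings.append(Finding(
                "GRID_MISMATCH",
                f"{name} shape {mask.data.shape} != image shape {case.image.data.shape}"))
        elif not np.allclose(case.image.spacing, mask.spacing, atol=SPACING_ATOL_MM):
            findings.append(Finding(
                "GRID_MISMATCH",
                f"{name} spacing {mask.spacing} != image spacing {case.image.spacing}"))
        vals = np.unique(mask.data)
        if not np.isin(vals, (0, 1)).all():
            findings.append(Finding("NONBINARY_MASK", f"{name} mask has values {vals[:10]}"))
    if case.kidney.count() == 0:
        findings.append(Finding("EMPTY_KIDNEY", "kidney mask has no voxels"))
    if case.tumor.count() == 0:
        findings.append(Finding("EMPTY_TUMOR", "tumor mask has no voxels"))
    if (case.kidney.data.shape == case.tumor.data.shape
            and np.any(case.kidney.data & case.tumor.data)):
        n = int(np.sum(case.kidney.data & case.tumor.data))
        findings.append(Finding("MASK_OVERLAP", f"{n} voxels labeled both kidney and tumor"))
    if any(s < 8 for s in case.image.data.shape):
        findings.append(Finding("GRID_TOO_SMALL",
                                f"grid {case.image.data.shape} below minimum (8,8,8)"))
    return findings


def resolve_overlap(kidney: LabelMask, tumor: LabelMask) -> LabelMask:
    """Make kidney and tumor disjoint: tumor wins on overlapping voxels."""
    overlap = kidney.data & tumor.data
    n = int(overlap.sum())
    if n:
        logger.warning("removing %d overlapping voxels from kidney (tumor wins)", n)
        return LabelMask(kidney.data & ~tumor.data.astype(bool), kidney.spacing, kidney.origin)
    return kidney
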