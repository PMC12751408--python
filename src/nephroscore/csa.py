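"""Tumor–parenchyma contact surface area (CSA).

The tumor surface is extracted with marching cubes at iso-level 0.5 on
the binary mask (vertices in physical mm).  A triangle belongs to the
contact surface when its centroid lies within a tolerance ``delta`` of a
kidney voxel center, evaluated on the exact Euclidean distance transform
of the kidney mask; ``delta`` defaults to one voxel diagonal.  Contact
triangle areas (half cross product) are summed and converted from mm^2
to cm^2 by dividing by 100.

The classical manual estimate assumes a spherical tumor cut by a plane:
``S = pi * R * h`` with R the tumor diameter and h the depth inside the
parenchyma, which is exactly the lateral area of the spherical cap,
``2 * pi * r * h``.

The 20 cm^2 low/high stratification threshold is applied to whatever CSA
value is passed in; reports record which method produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import marching_cubes

from .io_volumes import LabelMask

__all__ = [
    "SurfaceMesh",
    "CSAResult",
    "extract_surface_mesh",
    "compute_contact_area",
    "manual_csa",
    "stratify_csa",
    "export_mesh_ply",
    "CSA_THRESHOLD_CM2",
]

#: low/high CSA stratification threshold
CSA_THRESHOLD_CM2 = 20.0

_MIN_TRIANGLE_AREA_MM2 = 1e-9


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical mm (voxel-center coordinate frame)."""

    vertices: np.ndarray  # (n, 3) float mm
    triangles: np.ndarray  # (m, 3) int vertex indices

    def triangle_areas_mm2(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def triangle_centroids_mm(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def total_area_mm2(self) -> float:
        return float(self.triangle_areas_mm2().sum())


@dataclass
class CSAResult:
    contact_area_cm2: float
    total_tumor_surface_cm2: float
    contact_triangle_count: int
    stratum: str
    contact_tolerance_mm: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "contact_area_cm2": self.contact_area_cm2,
            "total_tumor_surface_cm2": self.total_tumor_surface_cm2,
            "contact_triangle_count": self.contact_triangle_count,
            "stratum": self.stratum,
            "contact_tolerance_mm": self.contact_tolerance_mm,
            "flags": list(self.flags),
        }


#: physical anti-aliasing scale applied to the binary field before
#: iso-extraction (mm).  Marching cubes on a raw binary mask inherits the
#: voxel staircase and overestimates curved surface areas by ~8-9%
#: irrespective of resolution; a sub-voxel Gaussian at the partial-volume
#: scale of CT removes the lattice bias while leaving voxel-aligned
#: planar faces essentially exact.
DEFAULT_ANTIALIAS_SIGMA_MM = 0.5


def extract_surface_mesh(mask: LabelMask, spacing=None,
                         antialias_sigma_mm: float = DEFAULT_ANTIALIAS_SIGMA_MM
                         ) -> SurfaceMesh:
    """Marching-cubes surface of a binary mask, vertices scaled to mm.

    The binary field is zero-padded (so surfaces touching the grid border
    are closed), anti-aliased with a Gaussian of ``antialias_sigma_mm``,
    and contoured at iso-level 0.5; degenerate (near-zero-area) triangles
    are dropped.  Vertex coordinates are voxel-center mm (index * spacing).
    """
    if mask.count() == 0:
        raise ValueError("cannot mesh an empty mask")
    spacing = tuple(float(s) for s in (spacing if spacing is not None else mask.spacing))
    idx = np.argwhere(mask.data)
    extents = idx.max(axis=0) - idx.min(axis=0) + 1
    if (extents < 2).any():
        raise ValueError("mask must be at least 2 voxels thick along every axis")
    sigma_vox = tuple(antialias_sigma_mm / s for s in spacing)
    pad = max(2, int(np.ceil(4.0 * max(sigma_vox, default=0.0))) + 1)
    field = np.pad(mask.data, pad).astype(np.float32)
    if antialias_sigma_mm > 0:
        field = ndi.gaussian_filter(field, sigma_vox)
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=spacing)
    verts = verts - pad * np.asarray(spacing)  # undo the pad offset
    mesh = SurfaceMesh(verts, faces.astype(np.int64))
    areas = mesh.triangle_areas_mm2()
    keep = areas > _MIN_TRIANGLE_AREA_MM2
    if not keep.all():
        mesh = SurfaceMesh(verts, mesh.triangles[keep])
    return mesh


def compute_contact_area(tumor: LabelMask, kidney: LabelMask,
                         spacing=None,
                         contact_tolerance_mm: float | None = None,
                         antialias_sigma_mm: float = DEFAULT_ANTIALIAS_SIGMA_MM
                         ) -> CSAResult:
    """Classify tumor-surface triangles against the kidney and sum contact area."""
    if kidney.count() == 0:
        raise ValueError("no parenchyma: CSA undefined")
    if tumor.count() == 0:
        raise ValueError("empty tumor")
    if tumor.data.shape != kidney.data.shape:
        raise ValueError("tumor and kidney masks are on different grids")
    if np.any(tumor.data & kidney.data):
        raise ValueError("tumor and kidney masks overlap; resolve before CSA")
    spacing = np.asarray(spacing if spacing is not None else tumor.spacing, float)
    if contact_tolerance_mm is None:
        contact_tolerance_mm = float(np.sqrt((spacing ** 2).sum()))

    mesh = extract_surface_mesh(tumor, spacing,
                                antialias_sigma_mm=antialias_sigma_mm)
    areas = mesh.triangle_areas_mm2()
    centroids = mesh.triangle_centroids_mm()

    edt = ndi.distance_transform_edt(~kidney.bool, sampling=tuple(spacing))
    # sample the distance map at centroid positions (mm -> fractional index)
    coords = (centroids / spacing).T
    dist = ndi.map_coordinates(edt, coords, order=1, mode="nearest")
    contact = dist <= contact_tolerance_mm

    contact_mm2 = float(areas[contact].sum())
    total_mm2 = float(areas.sum())
    flags: list[str] = []
    if not contact.any():
        flags.append("NO_CONTACT")
    contact_cm2 = contact_mm2 / 100.0
    return CSAResult(
        contact_area_cm2=contact_cm2,
        total_tumor_surface_cm2=total_mm2 / 100.0,
        contact_triangle_count=int(contact.sum()),
        stratum=stratify_csa(contact_cm2),
        contact_tolerance_mm=float(contact_tolerance_mm),
        flags=flags,
    )


def manual_csa(diameter_cm: float, depth_cm: float) -> float:
    """Spherical-crown estimate S = pi * R * h (cm^2): R diameter, h depth."""
    if diameter_cm <= 0:
        raise ValueError("diameter must be positive")
    if depth_cm < 0:
        raise ValueError("depth must be non-negative")
    if depth_cm > diameter_cm:
        raise ValueError("depth cannot exceed diameter (cap larger than sphere)")
    return math.pi * diameter_cm * depth_cm


def stratify_csa(area_cm2: float) -> str:
    """< 20 cm^2 -> low; >= 20 cm^2 -> high."""
    if area_cm2 < 0:
        raise ValueError("CSA cannot be negative")
    return "low" if area_cm2 < CSA_THRESHOLD_CM2 else "high"


def export_mesh_ply(mesh: SurfaceMesh, contact: np.ndarray, path) -> None:
    """Write a binary PLY of the tumor surface with contact faces colored red."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    colors = np.tile(np.array([[180, 180, 180, 255]], dtype=np.uint8),
                     (len(mesh.triangles), 1))
    colors[np.asarray(contact, bool)] = (220, 30, 30, 255)
    tm.visual.face_colors = colors
    tm.export(str(path), file_type="ply", encoding="binary")
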