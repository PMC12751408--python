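"""Synthetic CT kidney/tumor phantoms with ground truth.

Each phantom is a piecewise-constant HU field plus Gaussian noise:

* background fat/soft tissue (default -30 HU),
* a parenchymal kidney (default 150 HU, arterial-phase-like) that is
  either an ellipsoid (``boundary_mode="ellipsoid"``) or a half-space
  slab with a planar boundary (``"flat_slab"``),
* an optional coaxial inner sinus ellipsoid at fat attenuation
  (default -80 HU, inside the -110..0 HU sinus threshold),
* a spherical tumor (default 90 HU) partially protruding from the
  parenchyma.

The kidney mask is the kidney solid minus the tumor solid (disjoint
labels); the sinus is distinguishable only by attenuation, as in real
arterial-phase CT.  Noise goes into the image only — mask noise is
available separately through :func:`perturb_mask`.

Ground truth accompanies every case: the slab geometry has closed forms
(spherical-cap volume and lateral area), while the ellipsoid geometry
uses brute-force oracles (fine-grid volume sampling, dense surface
sampling) that are independent of the measurement code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .io_volumes import LabelMask, SegmentationCase, VoxelVolume
from . import renal_score as rs

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "perturb_mask",
    "flat_cap_spec",
    "ellipsoid_spec",
    "sample_margin_spec",
]

_HU_MIN, _HU_MAX = -1024.0, 3071.0


@dataclass
class PhantomSpec:
    """Full geometric and intensity description of one synthetic case."""

    grid_shape: tuple[int, int, int] = (112, 96, 112)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kidney_center: tuple[float, float, float] = (52.0, 46.0, 56.0)
    kidney_semiaxes: tuple[float, float, float] = (28.0, 24.0, 42.0)
    sinus_semiaxes: tuple[float, float, float] | None = (12.0, 10.0, 18.0)
    sinus_center: tuple[float, float, float] | None = None  # defaults to kidney_center
    tumor_radius: float = 15.0
    tumor_center: tuple[float, float, float] = (81.0, 46.0, 62.0)
    parenchyma_hu: float = 150.0
    sinus_hu: float = -80.0
    tumor_hu: float = 90.0
    background_hu: float = -30.0
    noise_sd: float = 15.0
    boundary_mode: str = "ellipsoid"  # ellipsoid | flat_slab
    slab_plane_z_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be positive")
        if self.boundary_mode not in ("ellipsoid", "flat_slab"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.boundary_mode == "flat_slab" and self.slab_plane_z_mm is None:
            raise ValueError("flat_slab mode requires slab_plane_z_mm")
        if self.sinus_center is None:
            self.sinus_center = self.kidney_center
        for hu in (self.parenchyma_hu, self.sinus_hu, self.tumor_hu,
                   self.background_hu):
            if not _HU_MIN <= hu <= _HU_MAX:
                raise ValueError(f"HU value {hu} outside [{_HU_MIN}, {_HU_MAX}]")
        if (self.boundary_mode == "ellipsoid" and self.sinus_semiaxes is not None
                and not all(s < k for s, k in
                            zip(self.sinus_semiaxes, self.kidney_semiaxes))):
            raise ValueError("sinus semiaxes must be smaller than kidney semiaxes")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical position of the last voxel center along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))


@dataclass
class PhantomTruth:
    """Analytic / brute-force ground truth for one phantom."""

    diameter_mm: float
    exophytic_fraction: float
    sinus_distance_mm: float  # inf when the phantom has no sinus
    polar_category: str
    crossing_fraction: float
    z_upper_mm: float
    z_lower_mm: float
    contact_area_cm2: float
    expected_points: tuple[int, int, int, int]
    expected_total: int
    expected_stratum: str

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(self.sinus_distance_mm):
            d["sinus_distance_mm"] = None
        d["expected_points"] = list(self.expected_points)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Continuous geometry helpers (truth side; independent of voxel code)
# ---------------------------------------------------------------------------

def _inside_kidney_fn(spec: PhantomSpec):
    if spec.boundary_mode == "flat_slab":
        zp = spec.slab_plane_z_mm

        def fn(pts: np.ndarray) -> np.ndarray:
            return pts[..., 2] <= zp
    else:
        c = np.asarray(spec.kidney_center)
        a = np.asarray(spec.kidney_semiaxes)

        def fn(pts: np.ndarray) -> np.ndarray:
            return (((pts - c) / a) ** 2).sum(axis=-1) <= 1.0
    return fn


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1 + math.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * math.pi * i / phi
    rho = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _cap_volume_below(center_z: float, r: float, z: float) -> float:
    """Volume of a sphere of radius r (center z) below the plane z = const."""
    h = np.clip(z - (center_z - r), 0.0, 2.0 * r)
    return math.pi * h * h * (3.0 * r - h) / 3.0


def _cap_volume_fraction(h: float, r: float) -> float:
    """Fraction of sphere volume in a cap of height h: h^2 (3r - h) / (4 r^3)."""
    h = float(np.clip(h, 0.0, 2.0 * r))
    return h * h * (3.0 * r - h) / (4.0 * r ** 3)


def exophytic_fraction_truth(spec: PhantomSpec, resolution_mm: float = 0.25) -> float:
    """Tumor volume fraction outside the kidney solid.

    Closed form (spherical cap) in flat_slab mode; fine-grid sampling of
    the tumor ball otherwise.
    """
    c = np.asarray(spec.tumor_center)
    r = spec.tumor_radius
    if spec.boundary_mode == "flat_slab":
        h_out = float(np.clip(c[2] + r - spec.slab_plane_z_mm, 0.0, 2.0 * r))
        return _cap_volume_fraction(h_out, r)
    ax = [np.arange(c[i] - r, c[i] + r + resolution_mm / 2, resolution_mm)
          for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    in_sphere = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r * r
    pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
    inside_kidney = _inside_kidney_fn(spec)(pts)
    n_t = int(in_sphere.sum())
    n_out = int((in_sphere & ~inside_kidney).sum())
    return n_out / n_t


def sinus_distance_truth(spec: PhantomSpec, resolution_mm: float = 0.25) -> float:
    """Minimum distance from the tumor sphere to the sinus ellipsoid surface.

    Brute force: the sinus surface is sampled on a dense angular grid
    (arc step ~ resolution_mm) and the sphere-to-point distance
    max(0, |p - c| - r) is minimized.  Returns 0 on overlap and inf when
    the phantom has no sinus.
    """
    if spec.sinus_semiaxes is None:
        return math.inf
    c = np.asarray(spec.tumor_center)
    r = spec.tumor_radius
    sc = np.asarray(spec.sinus_center)
    sa = np.asarray(spec.sinus_semiaxes)
    if ((((c - sc) / sa) ** 2).sum()) <= 1.0:  # tumor center inside sinus
        return 0.0
    n_th = max(90, int(math.pi * sa.max() / resolution_mm))
    n_ph = 2 * n_th
    th = np.linspace(0, math.pi, n_th)
    ph = np.linspace(0, 2 * math.pi, n_ph, endpoint=False)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    pts = np.stack([
        sc[0] + sa[0] * np.sin(TH) * np.cos(PH),
        sc[1] + sa[1] * np.sin(TH) * np.sin(PH),
        sc[2] + sa[2] * np.cos(TH),
    ], axis=-1).reshape(-1, 3)
    d = np.linalg.norm(pts - c, axis=1).min() - r
    return float(max(0.0, d))


def contact_area_truth(spec: PhantomSpec, n_directions: int = 60000) -> float:
    """Tumor surface area in contact with the kidney solid, cm^2.

    Closed form 2*pi*r*h_in (spherical-cap lateral area) in flat_slab
    mode; dense Fibonacci surface sampling otherwise.
    """
    c = np.asarray(spec.tumor_center)
    r = spec.tumor_radius
    if spec.boundary_mode == "flat_slab":
        h_in = float(np.clip(spec.slab_plane_z_mm - (c[2] - r), 0.0, 2.0 * r))
        return 2.0 * math.pi * r * h_in / 100.0
    dirs = _fibonacci_directions(n_directions)
    pts = c + r * dirs
    frac = float(_inside_kidney_fn(spec)(pts).mean())
    return 4.0 * math.pi * r * r * frac / 100.0


def polar_truth(spec: PhantomSpec) -> tuple[float, float, float, str]:
    """(z_upper, z_lower, crossing_fraction, category) for the phantom.

    Planes sit at the sinus craniocaudal extent; without a sinus they
    fall back to 75%/25% of the kidney z extent (mirroring measurement).
    The crossing fraction is the analytic sphere volume fraction between
    the planes.
    """
    if spec.sinus_semiaxes is not None:
        zc = spec.sinus_center[2]
        z_upper = zc + spec.sinus_semiaxes[2]
        z_lower = zc - spec.sinus_semiaxes[2]
    else:
        z_max_grid = spec.extent_mm[2]
        if spec.boundary_mode == "flat_slab":
            z0, z1 = 0.0, min(spec.slab_plane_z_mm, z_max_grid)
        else:
            z0 = max(0.0, spec.kidney_center[2] - spec.kidney_semiaxes[2])
            z1 = min(z_max_grid, spec.kidney_center[2] + spec.kidney_semiaxes[2])
        z_lower = z0 + 0.25 * (z1 - z0)
        z_upper = z0 + 0.75 * (z1 - z0)
    c_z, r = spec.tumor_center[2], spec.tumor_radius
    v = (4.0 / 3.0) * math.pi * r ** 3
    frac = (_cap_volume_below(c_z, r, z_upper)
            - _cap_volume_below(c_z, r, z_lower)) / v
    frac = float(np.clip(frac, 0.0, 1.0))
    return z_upper, z_lower, frac, rs.polar_category(frac)


def compute_truth(spec: PhantomSpec, oracle_resolution_mm: float = 0.25,
                  n_directions: int = 60000) -> PhantomTruth:
    """Assemble the full ground truth for a spec (no voxel grid involved)."""
    diameter = 2.0 * spec.tumor_radius
    exo = exophytic_fraction_truth(spec, oracle_resolution_mm)
    dist = sinus_distance_truth(spec, oracle_resolution_mm)
    z_upper, z_lower, frac, category = polar_truth(spec)
    contact = contact_area_truth(spec, n_directions)
    pts = (
        rs.points_for_radius(diameter),
        rs.points_for_exophytic(exo),
        1 if math.isinf(dist) else rs.points_for_nearness(dist),
        rs.points_for_polar(category),
    )
    total = sum(pts)
    return PhantomTruth(
        diameter_mm=diameter, exophytic_fraction=exo, sinus_distance_mm=dist,
        polar_category=category, crossing_fraction=frac,
        z_upper_mm=z_upper, z_lower_mm=z_lower, contact_area_cm2=contact,
        expected_points=pts, expected_total=total,
        expected_stratum=rs.stratify_renal(total),
    )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec,
                     oracle_resolution_mm: float = 0.25,
                     n_directions: int = 60000
                     ) -> tuple[SegmentationCase, PhantomTruth]:
    """Voxelize a phantom spec into a SegmentationCase and its ground truth.

    Deterministic given ``spec.seed``.  Raises when the tumor does not
    intersect the kidney solid (contact area undefined).
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    X = (np.arange(nx) * sx)[:, None, None]
    Y = (np.arange(ny) * sy)[None, :, None]
    Z = (np.arange(nz) * sz)[None, None, :]

    c = spec.tumor_center
    r = spec.tumor_radius
    tumor_solid = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= r * r

    if spec.boundary_mode == "flat_slab":
        kidney_solid = np.broadcast_to(Z <= spec.slab_plane_z_mm,
                                       (nx, ny, nz)).copy()
    else:
        kc, ka = spec.kidney_center, spec.kidney_semiaxes
        kidney_solid = (((X - kc[0]) / ka[0]) ** 2 + ((Y - kc[1]) / ka[1]) ** 2
                        + ((Z - kc[2]) / ka[2]) ** 2) <= 1.0

    if not np.any(tumor_solid & kidney_solid):
        raise ValueError("no contact: CSA undefined in phantom")

    image = np.full(spec.grid_shape, spec.background_hu, dtype=np.float32)
    image[kidney_solid] = spec.parenchyma_hu
    if spec.sinus_semiaxes is not None:
        scn, sa = spec.sinus_center, spec.sinus_semiaxes
        sinus_solid = (((X - scn[0]) / sa[0]) ** 2 + ((Y - scn[1]) / sa[1]) ** 2
                       + ((Z - scn[2]) / sa[2]) ** 2) <= 1.0
        image[sinus_solid & kidney_solid] = spec.sinus_hu
    image[tumor_solid] = spec.tumor_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd,
                                   spec.grid_shape).astype(np.float32)

    case = SegmentationCase(
        image=VoxelVolume(image, spec.spacing),
        kidney=LabelMask(kidney_solid & ~tumor_solid, spec.spacing),
        tumor=LabelMask(tumor_solid, spec.spacing),
        case_id=f"phantom-{spec.boundary_mode}-seed{spec.seed}",
    )
    truth = compute_truth(spec, oracle_resolution_mm, n_directions)
    return case, truth


def perturb_mask(mask: LabelMask, erosion_dilation_steps: int = 0,
                 flip_rate: float = 0.0, seed: int = 0) -> LabelMask:
    """Rater-noise model: morphological bias plus random boundary flips.

    Positive steps dilate, negative erode (6-connected, one voxel per
    step); then ``flip_rate`` of the boundary-adjacent voxels (either
    side of the surface) are toggled.  Deterministic given ``seed``.
    """
    if mask.count() == 0:
        raise ValueError("empty mask cannot be perturbed")
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    struct = ndi.generate_binary_structure(3, 1)
    m = mask.bool.copy()
    if erosion_dilation_steps > 0:
        m = ndi.binary_dilation(m, struct, iterations=erosion_dilation_steps)
    elif erosion_dilation_steps < 0:
        m = ndi.binary_erosion(m, struct, iterations=-erosion_dilation_steps)
    if flip_rate > 0:
        band = (ndi.binary_dilation(m, struct) & ~ndi.binary_erosion(m, struct))
        idx = np.argwhere(band)
        rng = np.random.default_rng(seed)
        k = int(round(flip_rate * len(idx)))
        if k:
            chosen = idx[rng.choice(len(idx), size=k, replace=False)]
            m[chosen[:, 0], chosen[:, 1], chosen[:, 2]] ^= True
    return LabelMask(m, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def flat_cap_spec(spacing_mm: float = 0.5, tumor_radius: float = 20.0,
                  depth_in_mm: float = 35.0, noise_sd: float = 15.0,
                  seed: int = 0) -> PhantomSpec:
    """Slab kidney with a spherical tumor of known intraparenchymal depth.

    The planar boundary sits ``depth_in_mm - tumor_radius`` above the
    tumor center, so the contact area is exactly the spherical-cap
    lateral area 2*pi*r*depth_in and the exophytic fraction is the
    closed-form cap volume fraction.
    """
    r = tumor_radius
    if not 0 < depth_in_mm <= 2 * r:
        raise ValueError("depth_in_mm must lie in (0, 2r]")
    lateral = 2 * r + 32.0
    cz = r + 8.0
    z_extent = cz + r + 8.0
    shape = tuple(int(round(e / spacing_mm)) + 1 for e in (lateral, lateral, z_extent))
    return PhantomSpec(
        grid_shape=shape,
        spacing=(spacing_mm,) * 3,
        tumor_radius=r,
        tumor_center=(lateral / 2, lateral / 2, cz),
        sinus_semiaxes=None,
        boundary_mode="flat_slab",
        slab_plane_z_mm=cz + (depth_in_mm - r),
        noise_sd=noise_sd,
        seed=seed,
    )


def ellipsoid_spec(seed: int = 0, spacing_mm: float = 1.0,
                   noise_sd: float = 15.0) -> PhantomSpec:
    """Default realistic preset: ellipsoidal kidney, coaxial sinus, lateral tumor."""
    return PhantomSpec(spacing=(spacing_mm,) * 3, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# Boundary-margin sampling for end-to-end recovery studies
# ---------------------------------------------------------------------------

#: acceptance bands keeping sampled geometry away from point-mapping
#: thresholds; chosen a priori from the voxel-discretization error budget
#: at 1 mm spacing (diameter: ~1 voxel; sinus distance: ~2 voxels plus
#: threshold dropout; polar fraction: slice quantization plus plane shift)
_DIAMETER_BANDS = ((26.0, 38.0), (42.0, 60.0))
_EXO_BANDS = ((0.05, 0.45), (0.55, 0.95))
_NEAR_MAX_LOW, _NEAR_MIN_HIGH = 1.2, 9.5
_POLAR_BANDS = ((0.08, 0.42), (0.58, 1.0))
_POLAR_CLEARANCE_MM = 3.0
_INTERIOR_CLEARANCE_MM = 2.5


def _in_bands(x: float, bands) -> bool:
    return any(lo <= x <= hi for lo, hi in bands)


def sample_margin_spec(seed: int, spacing_mm: float = 1.0,
                       oracle_resolution_mm: float = 0.5,
                       max_attempts: int = 400) -> PhantomSpec:
    """Sample an ellipsoid phantom whose geometry avoids point boundaries.

    Tumor size and placement are randomized, then the candidate's ground
    truth is evaluated with the brute-force oracles and rejected unless
    every component measurement sits safely away from its point-mapping
    threshold (margins above).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    base = ellipsoid_spec(seed=seed, spacing_mm=spacing_mm)
    kc = np.asarray(base.kidney_center)
    ka = np.asarray(base.kidney_semiaxes)
    extent = np.asarray(base.extent_mm)

    for _ in range(max_attempts):
        lo, hi = _DIAMETER_BANDS[rng.integers(len(_DIAMETER_BANDS))]
        r = rng.uniform(lo, hi) / 2.0
        theta = rng.uniform(0, 2 * math.pi)
        psi = rng.uniform(-0.55, 1.05)
        u = np.array([math.cos(theta) * math.cos(psi),
                      math.sin(theta) * math.cos(psi),
                      math.sin(psi)])
        rho = 1.0 / math.sqrt(float(((u / ka) ** 2).sum()))
        t = rng.uniform(-0.9 * r, 0.45 * r)
        c = kc + (rho + t) * u
        if np.any(c - r < 2.0) or np.any(c + r > extent - 2.0):
            continue
        cand = PhantomSpec(
            grid_shape=base.grid_shape, spacing=base.spacing,
            kidney_center=tuple(kc), kidney_semiaxes=tuple(ka),
            sinus_semiaxes=base.sinus_semiaxes,
            tumor_radius=float(r), tumor_center=tuple(float(v) for v in c),
            noise_sd=base.noise_sd, seed=seed,
        )
        # cheap checks first: polar, then sinus distance, then exophytic
        z_upper, z_lower, frac, _ = polar_truth(cand)
        if frac == 0.0:
            clear = min(abs(c[2] - r - z_upper), abs(z_lower - (c[2] + r)))
            if (z_lower < c[2] + r and c[2] - r < z_upper) or \
                    clear < _POLAR_CLEARANCE_MM:
                continue
        elif not _in_bands(frac, _POLAR_BANDS):
            continue
        d = sinus_distance_truth(cand, oracle_resolution_mm)
        if not (d <= _NEAR_MAX_LOW or d >= _NEAR_MIN_HIGH):
            continue
        if d == 0.0 and not _sinus_poles_clear(cand):
            continue
        exo = exophytic_fraction_truth(cand, oracle_resolution_mm)
        if exo == 0.0:
            if not _interior_clearance_ok(cand):
                continue
        elif not _in_bands(exo, _EXO_BANDS):
            continue
        if exo >= 1.0:  # must intersect the kidney
            continue
        return cand
    raise RuntimeError(f"no margin-compliant phantom found for seed {seed}")


def _interior_clearance_ok(spec: PhantomSpec,
                           clearance: float = _INTERIOR_CLEARANCE_MM) -> bool:
    """All points of the inflated tumor sphere remain inside the kidney."""
    dirs = _fibonacci_directions(2000)
    pts = np.asarray(spec.tumor_center) + (spec.tumor_radius + clearance) * dirs
    return bool(_inside_kidney_fn(spec)(pts).all())


def _sinus_poles_clear(spec: PhantomSpec, cap_mm: float = 3.0,
                       clearance: float = 2.0) -> bool:
    """When tumor and sinus overlap, the sinus craniocaudal tips must stay clear.

    Otherwise the tumor would truncate the measured sinus z extent and
    move the polar planes relative to the analytic truth.
    """
    sc = np.asarray(spec.sinus_center)
    sa = np.asarray(spec.sinus_semiaxes)
    th = np.linspace(0, math.pi, 400)
    ph = np.linspace(0, 2 * math.pi, 200, endpoint=False)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    pts = np.stack([
        sc[0] + sa[0] * np.sin(TH) * np.cos(PH),
        sc[1] + sa[1] * np.sin(TH) * np.sin(PH),
        sc[2] + sa[2] * np.cos(TH),
    ], axis=-1).reshape(-1, 3)
    near_tip = np.abs(pts[:, 2] - sc[2]) > (sa[2] - cap_mm)
    if not near_tip.any():
        return True
    dist = np.linalg.norm(pts[near_tip] - np.asarray(spec.tumor_center), axis=1)
    return bool((dist - spec.tumor_radius).min() >= clearance)
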