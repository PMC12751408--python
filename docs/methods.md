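# Methods

This note documents the geometric and statistical procedures, the
choices made where the definitions were open, and what the synthetic
validation does and does not establish.

## Grid conventions

Volumes and masks live on a shared voxel lattice with array axes
(x, y, z) = (left–right, anterior–posterior, inferior–superior); NIfTI
inputs are reoriented to the closest RAS-canonical orientation on load
so that "axial slice" and "craniocaudal axis" are unambiguous. Physical
coordinates are voxel centers, `origin + index * spacing` (mm). All
distances are voxel-center Euclidean distances computed with exact
distance transforms. Kidney and tumor labels are kept disjoint; on
overlapping inputs the tumor wins and the overlap is removed from the
kidney with a warning. The kidney label is taken to be the full kidney
contour: the sinus is interior to it and distinguishable by attenuation
only, as in contrast-enhanced CT.

Preprocessing utilities mirror common segmentation-training
conventions: trilinear (image) / nearest-neighbor (label) resampling to
a target spacing, a cohort median-spacing helper, and CT windowing
(default width 400 HU at level 30 HU, i.e. clip to [−170, 230] HU)
followed by Z-scoring. Scoring itself runs on the native grid and on
calibrated HU — window-normalized images must not be fed to the sinus
threshold.

## R.E.N.A.L. measurements

**R — maximum diameter.** The largest 26-connected tumor component
(ties broken by the lexicographically lowest (z, y, x) seed voxel) is
reduced to its voxel-center point cloud; the oriented bounding box is
taken along the principal axes of the cloud and the longest edge is the
diameter. On digitized spheres and rotated boxes this recovers the true
longest dimension to within about one voxel diagonal. A single-voxel
tumor returns `max(spacing)` with a warning.

**E — exophytic fraction.** The parenchymal envelope (the kidney
contour as it would be without the tumor-shaped defect) must be
reconstructed before the protruding volume can be measured. Three
builders are provided; the mode used is recorded in every report.

* `slice-ellipse` (default): on each axial slice in the tumor's
  z-range, an ellipse is least-squares fitted to the boundary of the
  hole-filled kidney cross-section after discarding boundary pixels
  within two dilation steps of the tumor (the carved, tumor-facing
  surface); the envelope is the union of the kidney and the fitted
  interior, hole-filled. The fit falls back to the hull bridge
  (below) when fewer than 20 intact boundary pixels remain or the
  fitted axes are inconsistent with the observed extent (outside
  [0.25, 3]× the slice semi-extent).
* `slice-hull`: per-slice 2D convex hull of kidney plus
  kidney-adjacent tumor voxels.
* `3d-hull`: a single 3D convex hull.

The default deviates from the simpler hull because a convex hull
bridges the excision defect with a straight chord, while the true
contour bulges outward; across a wide defect the missing lens inflates
the measured exophytic fraction by up to ~0.1. A rolling-disk
morphological closing was evaluated and rejected: a wide, shallow
defect admits the structuring disk through its mouth, so closing cannot
fill it at any radius that leaves the rest of the contour intact.
Tumor voxels on slices containing no kidney are exophytic by
definition.

**N — sinus distance.** The renal sinus is segmented by thresholding
−110 ≤ HU ≤ 0 inside the hole-filled kidney and keeping the largest
26-connected component; an empty result is valid and is reported as
`NO_SINUS` (N then scores 1 point rather than failing). The distance is
the minimum over tumor voxels of the exact Euclidean distance transform
of the sinus complement, which equals the brute-force all-pairs minimum
between voxel centers exactly; overlap gives 0.

**L — polar relation.** The polar planes are the axial planes at the
superior- and inferior-most sinus voxel centers (standard nephrometry
convention); without a sinus they fall back to 75%/25% of the kidney's
craniocaudal extent. The crossing fraction is the fraction of tumor
voxel centers strictly between the planes: 0 → entirely polar (1 pt),
(0, 0.5] → crosses (2 pts), > 0.5 → central (3 pts). The axial-midline
special case of the original clinical rule is not separately detected;
it is subsumed by the > 50% rule.

**Point mapping ties.** The prose definitions are ambiguous at exact
threshold values; the implementation fixes them as R: ≤ 40 → 1,
≥ 70 → 3; E: ≥ 0.5 → 1, = 0 → 3; N: ≥ 7 → 1, ≤ 4 → 3; fraction-0.5
polar → crosses. These choices are deterministic and recorded; totals
4–6/7–9/10–12 map to low/moderate/high.

## Contact surface area

The tumor mask (full tumor, including any exophytic part) is
zero-padded, anti-aliased with a Gaussian of fixed physical scale
σ = 0.5 mm, and contoured with marching cubes at iso-level 0.5;
vertices are in voxel-center mm. Degenerate triangles (< 1e−9 mm²) are
dropped. A triangle is *contact* if its centroid lies within a
tolerance δ of a kidney voxel center, evaluated by trilinear sampling
of the kidney's exact Euclidean distance transform; δ defaults to one
voxel diagonal √(sx²+sy²+sz²) and is recorded in the result. Contact
area is the sum of contact-triangle areas (half cross product) / 100
(cm²).

Why the anti-aliasing: marching cubes applied to a raw binary mask
tracks the voxel staircase, overestimating curved surface areas by a
resolution-independent ~8–9%. Anti-aliasing at a fixed sub-voxel
physical scale removes the lattice bias while leaving voxel-aligned
planar faces essentially exact (a 20 mm cube at 1 mm voxels measures
within 5% of 6a²; a digitized 15 mm-radius sphere at 0.5 mm within
0.1% of 4πr²), and makes the cap-phantom CSA error shrink monotonically
as voxels go 2 → 1 → 0.5 mm (≈ 12% → 6% → 1.3%). This is field-level
anti-aliasing inside the surface extractor, not a mesh
smoothing/remeshing stage. Because σ is a physical length, joint
rescaling of geometry and voxel size is exactly area-equivariant only
when σ (and δ) are rescaled with it; both are exposed parameters.

The residual positive bias of the mesh CSA comes mostly from the
tolerance band at the contact rim (a strip of width ≈ δ), so it scales
with voxel size and with the rim shallowness; on the slab phantom at
0.5 mm it is ≈ 1.3%.

`manual_csa(R, h) = πRh` is the classical spherical-crown estimate
(R = diameter in cm, h = intraparenchymal depth in cm); it is
algebraically identical to the cap lateral area 2πrh and exact on the
slab phantom. Stratification applies the 20 cm² threshold to whichever
CSA value is passed; reports record which method produced it.

## Synthetic phantoms and ground truth

A phantom is a piecewise-constant HU field plus i.i.d. Gaussian noise:
background −30 HU, parenchyma 150 HU (arterial phase), sinus −80 HU
(inside the −110..0 threshold), tumor 90 HU, noise SD 15 HU — values
chosen once as typical contrast-CT magnitudes. The kidney is an
ellipsoid (default semi-axes 28×24×42 mm with a coaxial 12×10×18 mm
sinus) or, for closed-form validation, a half-space slab whose planar
boundary sets the tumor's intraparenchymal depth exactly. The tumor is
a sphere; the kidney mask is the kidney solid minus the tumor. Noise
enters the image only; mask noise is modeled separately by
`perturb_mask` (morphological bias ± boundary flips), which is what the
κ machinery is validated on.

Ground truth is computed independently of the measurement code: slab
mode uses the closed forms (cap lateral area 2πrh_in, cap volume
fraction h²(3r−h)/(4r³), analytic plane positions); ellipsoid mode uses
brute-force oracles — fine-grid volume sampling for the exophytic
fraction, dense angular sampling of the sinus surface for the minimum
distance, Fibonacci-lattice surface sampling for the contact area — at
0.25 mm default resolution (0.5 mm in the 100-phantom study).
`expected_points` always equals the point mapping applied to the truth
geometry.

The end-to-end recovery study samples 100 ellipsoid phantoms at 1 mm
voxels with geometry rejected unless every measurement sits away from
its point threshold: diameter in [26, 38] ∪ [42, 60] mm; exophytic
fraction exactly 0 (with ≥ 2.5 mm interior clearance) or in
[0.05, 0.45] ∪ [0.55, 0.95]; sinus distance ≤ 1.2 mm or ≥ 9.5 mm;
polar fraction in [0.08, 0.42] ∪ [0.58, 1] or plane clearance ≥ 3 mm.
The bands are derived from the voxel-discretization error budget at
1 mm spacing (≈ 1 voxel for diameters, ≈ 2–3 voxels for center-to-center
distances plus threshold dropout under noise, slice quantization plus
sinus-tip dropout for the polar planes). Problem sizes throughout
(≈ 1–2.5 M-voxel grids, 100 phantoms, 10⁴ rating pairs, 1000 null
replicates) were chosen so the whole validation runs in minutes on one
CPU while keeping Monte-Carlo error well inside the asserted
tolerances.

What passing these phantoms shows — and does not. The phantoms have
exact spheres/ellipsoids, uniform attenuation, no partial-volume
ramps, no perinephric structures, vessels or collecting system, and a
single tumor. Success establishes that the geometry-to-points
machinery is correct and convergent on known shapes; it says nothing
about segmentation quality on real CT, about irregular tumor shapes, or
about whether the sinus-extent polar convention matches any particular
clinical rater.

## Statistics

Weighted κ uses agreement weights 1 − |i−j|/(k−1) (linear, default) or
1 − ((i−j)/(k−1))² (quadratic); the large-sample standard error is the
Fleiss–Cohen–Everitt formula and the 95% CI is κ ± 1.96·SE clipped to
[−1, 1]. κ is undefined (error) when chance agreement is 1. Group
comparisons are rank-based: two groups → two-sided Mann–Whitney U
(normal approximation, tie-corrected); ≥ 3 groups → tie-corrected
Kruskal–Wallis with Dunn's pairwise z tests, Holm-adjusted by default
(Bonferroni available). Quartiles are linear-interpolation (type 7) so
reported medians/IQRs are reproducible. Outcome tables assign strata
via the R.E.N.A.L. or CSA rule, report n(%), per-stratum median (IQR),
one test per outcome column, and handle missing outcome values by
per-column complete-case analysis with exclusion counts. A degenerate
comparison (all values identical) reports p = 1 with a flag rather than
failing.

## Known limitations

* The parenchymal-envelope default assumes approximately elliptical
  axial cross-sections; strongly bean-shaped or duplex kidneys will be
  served better by `slice-hull`, and agreement of any envelope builder
  with human raters of E is an open question.
* The sinus threshold assumes calibrated HU and contrast-enhanced
  parenchyma; on unenhanced images the sinus may be missed (degrades
  visibly to `NO_SINUS`, N = 1).
* CSA depends on the recorded tolerance δ; values computed at different
  voxel sizes are comparable only as δ shrinks with the voxel.
* Single tumor per kidney; multifocal disease is out of scope.
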