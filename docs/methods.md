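# Methods

## Geometry and coordinate conventions

World coordinates are millimetres, right-handed; voxel indices are 0-based
and a voxel's world position is the position of its center (the NIfTI
convention). The applicator's main axis is assumed parallel to the grid
z-axis; all slice-wise processing happens on axial planes perpendicular to
it. A 2D imaging plane that contains the axis covers **two** half-planes, θ
and θ+180°, so a series of 8 slice orientations spaced 22.5° yields 16
half-plane angular samples — the angular grid both the population map and
the contour extraction operate on.

Cylinder coordinates use r = √((x−x_c)² + (y−y_c)²) and θ = atan2(y−y_c,
x−x_c) mapped to [0, 360), with θ = 0 defined for points exactly on the
axis. Only the relative angular origin matters anywhere in the pipeline, so
the atan2 argument order is a pure convention; it is fixed once here and
used consistently.

## Thermometry and thresholding

PRFS constants default to α = −0.01 ppm/°C, γ = 42.58 MHz/T, B₀ = 1.5 T,
TE = 3.69 ms, baseline 20 °C (room-temperature ex vivo phantom); all are
configurable. Phase differences are wrapped to (−π, π] before scaling, which
is unambiguous while true heating stays inside the ±π window (≈ ±212 °C at
these constants — never binding here).

Necrosis is the critical-temperature model: mask = {T ≥ τ} (inclusive ≥,
fixed by convention), restricted to a 60×60 mm ROI around the applicator and
reduced to the largest 8-connected component (26-connected in 3D). The
optimal-threshold search scans 0–100 °C at 0.5 °C steps — below the ±1 °C
temperature accuracy of the acquisition it emulates — maximizing slice-wise
Dice against the resliced ground truth, ties resolved toward the larger
threshold. Threshold policies: *global* (one value), *median* (median of the
eight per-orientation optima; robust to any single corrupted optimum),
*local* (per-orientation optima as-is; unsupported by the interpolation
backend, whose necrosis estimate is thresholded on the fused volume), and
*ground truth* (resliced ground-truth masks as perfect input; not applicable
to the interpolation backend, since resliced masks carry no temperatures).

## Outlier rejection

Necrosis only grows, so for each orientation the area of the current
(component-denoised) mask is compared with the most recent **accepted** mask
of that orientation; |ΔA| > 80 % (strict) flags the slice. Comparing against
the last accepted frame rather than the raw previous frame keeps one
corrupted frame from flagging the healthy frame after it. The 80 % value is
an empirical rule and is exposed as a parameter. Shrinkage beyond the rule
is likewise flagged (absolute value): under the growth assumption it is just
as anomalous. By default the filter protects the three shape backends;
the interpolation baseline runs unfiltered, matching its original design —
this asymmetry is exactly what the robustness comparison measures.

## Reconstruction backends

**Temperature interpolation.** A population map, computed once per geometry,
brackets every voxel's azimuth between its two nearest half-planes (wrapping
across 360°→0°) and stores complementary weights w = 1 − Δθ/Δθ_gap — the
*nearer* plane gets the *larger* weight, so the fused field is continuous
across acquired planes, and a voxel exactly on a plane takes that plane's
temperature unchanged. Each voxel samples both partners at its (r, z) by
nearest neighbor along the half-plane, blends, and falls back to baseline
outside the ROI cylinder (the I_w indicator) or when both partners are
missing. The volume is thresholded in 3D and reduced to its largest
26-connected component.

**Delaunay hull.** Necrotic pixels from all accepted orientations form a 3D
point cloud (reduced, without loss, to per-slice morphological boundary
pixels — interior points cannot be hull vertices). A Bowyer–Watson
incremental triangulation is built inside a super-tetrahedron placed ~10³
cloud-extents away: per insertion, all tetrahedra whose circumsphere contains
the point are carved out and the cavity boundary is re-triangulated to the
point; super-vertex cells are removed at the end, and faces belonging to
exactly one remaining cell form the convex hull. Voxel-grid degeneracies
(collinear/cospherical configurations everywhere) are broken by a
deterministic seeded jitter of ~1e-8 of the cloud extent; reported vertices
are the unjittered originals. Voxelization is a half-space test of voxel
centers against outward face planes with a 1e-7 boundary-inclusive
tolerance.

**Minimum-area enclosing ellipses.** Per axial slice, Khachiyan's
first-order algorithm on the lifted dual: iterate the point weights until
max M_j ≤ (d+1)(1+ε) with ε = 1e-4 (1000 iterations cap), then A =
(1/d)(Σu_i P_i P_iᵀ − ccᵀ)⁻¹. After convergence A is rescaled by the largest
quadratic form among the inputs whenever that exceeds 1, making enclosure
exact at a negligible area cost. Radii and orientation come from the
symmetric eigendecomposition of A (r_i = 1/√λ_i). Fewer than 3 points or a
numerically collinear level (e.g. a single surviving orientation) yields an
empty slice. Pixel fill is inclusive (quadratic form ≤ 1).

**Closed splines.** Per axial slice, the outermost necrotic point of each
half-plane direction is the contour vertex set; vertices are sorted by
ascending θ (ties by ascending r, then input order) and interpolated by a
*periodic cubic B-spline* — the cyclic (1 4 1)/6 system gives the control
points, and evaluation uses de Boor's recursion on the uniform periodic knot
grid. (The C² periodic cubic interpolant is unique, which the tests exploit
by comparing against an independent construction.) The curve is densely
sampled into a polygon at half-voxel spacing and pixels are classified by
Sunday's winding-number test. Pixels exactly on the boundary count as
inside; because the polygon's chords lie up to one sagitta inside the smooth
curve, the boundary tolerance is set to the worst-case chord sagitta
(spacing²/8 at 1 mm curvature radius) rather than machine epsilon —
otherwise every contour-vertex pixel would be spuriously excluded.

## The synthetic phantom generator

The generator emulates the phantom experiments end to end: 8 orientations of
256×256 px slices at 1.0×1.0 mm in-plane / 5 mm thickness (defaults; tests
use smaller grids), a 900 s ablation with necrosis semi-axes growing as
√(t/T) to (14, 14, 22) mm, per-orientation coagulation thresholds drawn from
[50, 60] °C (the pH-driven inhomogeneity of bio-protein phantoms, modeled as
180°-periodic angular sectors so both half-planes of a slice share one
threshold), ±1 °C Gaussian noise plus stronger (8 °C) background noise
outside the 60×60 mm ROI, and scheduled low-SNR outlier slices corrupted by
half-normal noise of 50 °C sd — far above the 8-connected percolation
threshold, so the thresholded area reliably inflates far beyond the 80 %
rule.

The temperature model is a Gaussian in the scaled elliptic radius,
normalized so that T(ρ=1) equals the sector's threshold — **not** a bioheat
solution. The reconstruction algorithms consume only thresholded masks, so
only the level sets must be realistic; by construction, thresholding the
noiseless field at the construction threshold reproduces the analytic
ground-truth mask exactly, which anchors the threshold-recovery tests.

The heat-sink vessel is a straight 5 mm tube with 1 mm wall, by default
crossing the applicator axis region perpendicularly (as tubes are physically
inserted into a phantom); a z-parallel orientation is also supported. Inside
the cooling radius the field ramps from baseline at the tube wall to τ−1 °C
at the cooling boundary, so the τ-level set is dented exactly there and
*lower* applied thresholds only thin the sheath — they never dissolve the
dent (a flat just-below-τ clamp would vanish under the median policy's
pooled threshold and under noise). The protective margin beyond the wall
defaults to 0.5 mm: thin enough that reconstructions must approach the tube
closely, consistent with experiments in which ablation demonstrably affects
inserted tubes. The ground truth is the analytic ellipsoid minus the full
cooling sheath, so ground truth ∩ tube = ∅ by construction.

What the generator does **not** emulate: bioheat physics (perfusion,
conduction transients), B₀ drift, motion, partial-volume and slice-profile
effects, the sub-lethal transition zone, and irregular (non-ellipsoidal)
necrosis shapes. Passing tests therefore demonstrate correctness of the
geometry and of the comparative mechanisms, not clinical accuracy on real
lesions.

## Study conditions used by tests and the acceptance script

Problem sizes are the package's own choices for a desk-scale study:

* unit/property tests run on 24³–64³ grids;
* the perfect-input (resliced ground truth) comparison uses three noiseless
  convex phantoms at 96³ with in-plane aspect ratio 2 (semi-axes such as
  12×24×30 mm) — on exactly axisymmetric phantoms all backends agree to
  within voxelization noise, whereas anisotropy separates them by mechanism:
  the enclosing ellipse recovers an elliptical cross-section exactly, the
  interpolating spline errs ~quartically in vertex spacing, and the hull's
  inscribed chords err quadratically;
* the parameter-recovery check runs one noiseless 128³ phantom;
* the adaptability study uses four perfusion phantoms (64³, perpendicular
  tubes at varying azimuth/height, median policy, ±1 °C noise);
* the robustness study corrupts one slice at the final timepoint over three
  seeds.

Acquisition timestamps are sampled geometrically (area growth between
consecutive frames ≈ 30–40 %, safely below the 80 % outlier rule — the live
protocol images every ~1 s, which desk-scale runs subsample) with a densened
tail (855 s, 900 s) so that an outlier-replaced frame is nearly current, as
it would be live.

## Numerical choices and degenerate inputs

* Khachiyan tolerance 1e-4 (1e-5–1e-7 in exactness tests), deterministic.
* Delaunay jitter 1e-8 of cloud extent, seeded; hull fill tolerance 1e-7.
* Spline polygon sampling at half the voxel size; boundary tolerance
  spacing²/8.
* Degenerate levels (fewer than 3 points, collinear points) yield empty
  slices rather than errors; a fully degenerate cloud (< 4 points or
  coplanar) aborts the Delaunay backend with an explicit error.
* Dice of two empty masks is 1 by convention; exactly one empty gives 0.
* The SEM half-width uses the normal 1.96 quantile by default; the Student-t
  quantile is available (`use_t=True`).
* All randomness (phantom noise, jitter) flows through seeds recorded in the
  spec/provenance; reruns are bit-identical.

## Known limitations

* The applicator axis must be parallel to the grid z-axis; oblique axes and
  non-uniform angular sampling are out of scope.
* Slice z-spacing must match the reconstruction grid's z-spacing (slices are
  acquired in-plane with the axis, so this is the natural sampling).
* The spline contour extraction (outermost point per half-plane) assumes a
  star-shaped region about the axis; strongly non-star-shaped necrosis would
  need a different contour operator (the rule is configurable in principle
  but only this one is implemented).
* The Bowyer–Watson implementation targets desk-scale clouds (≲ 10⁴ points
  after contour reduction); it is O(n·cells) per insertion, not the
  accelerated variant.
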