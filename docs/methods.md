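# Methods

This note documents the models, conventions and numerical choices behind
`renalmold`, what the synthetic phantom does and does not emulate, and the
known limitations.

## Coordinate conventions

World coordinates are millimetres in the RAS+ frame of the NIfTI affine;
volumes are reoriented to the closest canonical orientation on load. Voxel
indices are 0-based and refer to voxel centers. The mold frame is a
right-handed orthonormal triad (normal, lateral, up) with `lateral = up ×
normal`; array axis 0 runs along the slice normal, axis 2 along `up` (out of
the open mold top). After resampling, the lattice affine maps indices to
*frame* millimetres, so all carving and QC work in one axis-aligned frame.

## Sectioning frame and base roll

Transverse sectioning uses the pole axis itself as the knife-plane normal,
oriented from the lower toward the upper pole so slice labels increase
footward-to-headward. Longitudinal sectioning uses
`normal = unit(a × (c − lower))`, which makes every cut plane contain the
pole axis and the tumor centroid; the centroid plane then contains both
poles exactly. A centroid collinear with the pole axis leaves the
longitudinal plane undefined and raises an error suggesting transverse mode.

The roll about the normal places the two base anchors (hilum, tumor contact
point). The objective — the summed height of the two anchors above the
lowest outline point along `−up` — has no useful closed form because the
lowest outline point changes discontinuously with the roll, so the roll is
found by exhaustive search on a uniform 1° grid (ties broken toward the
smallest rotation, then the positive angle). The minimum over outline points
is evaluated on the convex-hull vertices of the outline's boundary voxels,
which is exact for this objective and keeps the 360-angle sweep cheap. When
both anchors lie on the sectioning axis the objective is flat in the anchor
term; the roll is left at 0 with a warning.

Masks are resampled nearest-neighbor (labels must not blend), parameter maps
trilinearly. The default mold-frame spacing is 1 mm isotropic —
sub-millimetric relative to printer accuracy while keeping desk-scale grids
(a full-size phantom mold occupies roughly 170 × 120 × 95 voxels). At a
target spacing at or below the source spacing, per-mask volume is preserved
within 5% (checked, warned otherwise; a vanished mask is an error).

## Mold construction

All carving is boolean arithmetic on the voxel occupancy grid; the mesh is
extracted once at the end. This sidesteps the robustness problems of mesh
CSG and makes every geometric invariant testable by direct voxel scan.

* **Smoothing.** The outline is Gaussian-blurred (default σ = 2 mm) and
  re-thresholded at 0.5. Thresholded Gaussian smoothing moves boundaries by
  approximately σ²·κ (mean-curvature motion): a 20 mm sphere at σ = 2 mm
  loses about 3% of its volume, and thin fat caps are rounded. The unit
  tests assert agreement with this continuum prediction rather than
  pretending the step is volume-exact.
* **Cavity.** For every footprint column the block is emptied from the
  smoothed outline's lowest surface to the top (vertical-shadow carve). This
  guarantees by construction that a rigid specimen can be lowered in
  vertically; the price is that overhanging recesses below the widest
  cross-section ("waterline") are not reproduced. The outline floor rests
  `base_thickness_mm` (default 10) above the block bottom; walls are
  `block_margin_mm` (default 10) wide.
* **Slots.** Knife planes sit at `offset + k · slice_spacing_mm` covering
  the tumor extent plus one margin plane per side; labels count from the
  lower end. Slots are `slot_width_mm` (default 2) wide and stop
  `slot_bridge_mm` (default 5) above the block bottom so the mold stays in
  one piece while the knife clears the specimen. Slot edges are snapped to
  the voxel grid (center offset ≤ half a voxel, reported); consecutive slot
  centers are exactly one slice pitch apart. The default pitch of 5 mm
  matches a typical axial T1w slice spacing and is configurable; when the
  input affine has an axis within ~8° of the sectioning normal the plan
  offset is anchored so planes coincide with acquisition slice centers.
* **Guide comb.** The block extends `guide_depth_mm` (default 15) on the
  +lateral side and is slotted identically; the tooth after slot *k* carries
  *k* tick-mark notches (1 mm ticks, 2 mm deep) cut into its top edge along
  the comb depth. Tick marks replace embossed numerals: they are countable
  by touch and sight and trivially printable.
* **Landmark holes.** Two vertical cylinders of `hole_diameter_mm` (default
  20) are drilled at the frame (normal, lateral) coordinates of the hilum
  and the tumor contact point. Under the specimen footprint the hole opens
  into the cavity; where the disc overlaps a wall only the base thickness is
  drilled. A disc that leaves the block footprint entirely is an error
  naming the offending landmark.

The final mesh is produced by marching cubes on the occupancy grid, then
simplified in the order face reduction → (optional) isotropic remeshing →
(optional) Laplacian → Taubin. Decimation is quadric edge collapse
(Garland–Heckbert plane quadrics, placement restricted to endpoints and
midpoint) with a manifold link-condition check and a normal-flip rejection,
which preserves watertightness; a small edge-length term (10⁻²·|e|²)
regularizes the zero-cost ties of flat regions so coarsening stays uniform.
Taubin smoothing alternates `p ← p + λΔp` and `p ← p + μΔp` on the
uniform-weight Laplacian with λ = 0.5, μ = −0.53, 10 iterations after
decimation to 20,000 faces: enough to remove voxel staircase without
visible shrinkage (≤ 2% volume change on spheres, against > 5% for the same
number of pure Laplacian iterations).

Iso-surfacing convention: marching cubes on binary data renders an isolated
voxel as the inscribed octahedron (1/6 of the voxel volume); an optional
order-0 supersampling factor *m* moves the surface toward the voxel cube
(volume ≈ 0.92 of the cube at m = 4). Large blobs are within ~1% of their
voxel volume either way, so the pipeline uses m = 1.

## Validation metrics

The physical study this emulates compared photographed tissue sections with
the MRI contours of the matching slice. A phantom cannot be photographed, so
the package scores the geometry the mold itself imposes: at each slot plane
the *cavity cross-section* — per column, the span from the carved cavity
floor to the specimen's top surface — is compared against the raw outline
cross-section with the Dice coefficient. In this comparison the only error
sources are the Gaussian smoothing and the shadow carve, which is exactly
the mold's contribution to coregistration error; specimen positioning is
perfect by construction, so these values are not comparable to patient DSCs
(which include placement, deformation and manual photo alignment). Planes
that merely graze the anatomy tangentially produce near-empty sections on
which the coefficient is uninformative (a sphere-tangent plane scores 0 on
3 voxels); such planes are handled without error, flagged via
`crosses_tumor`, and the ≥ 0.95 property is asserted on planes through the
tumor — the planes on which the physical validation sections were cut.

QC further checks mesh watertightness and winding consistency, the
insertability invariant (above the base, no solid voxel above an empty one
in any column — equivalent to a brute-force per-column scan), hole center
error and equivalent-area opening diameter, and the worst interslot spacing
deviation.

## The phantom

`make_anatomy` builds an ellipsoidal kidney (default semi-axes 22 × 30 ×
55 mm, tilted 15° off the scanner axes), a spherical tumor (default radius
25 mm) bulging antero-medially from the kidney surface, a hemispherical
hilum notch on the medial side, and a perinephric fat shell whose thickness
varies smoothly with direction (default 4–12 mm) and thins to designated
contact points (2 mm over the tumor bulge apex, 3 mm at the kidney contact).
The two base anchors end up ~60° apart in azimuth about the pole axis, which
is what makes a single base orientation expose both — the configuration the
landmark system presumes. Landmarks are analytic (poles at the long-axis
extremes, hilum at the notch center, contacts at the fat minima) and stored
in the ground-truth record together with every generating parameter.
Optional tumor lobulation applies a seeded traceless quadratic form to the
radius (a real ℓ = 2 harmonic); the default amplitude is 0 so sphere oracles
stay exact. Default lattice spacing is 1.5 mm, a realistic T1w resolution.

`make_parameter_maps` partitions the tumor into concentric habitat shells
(defaults: necrotic core to 0.5 of the radius, transition rim to 0.8,
perfused periphery to 1.0) and draws each channel i.i.d. from the region's
normal distribution. The default means mirror the expected contrast of a
necrotic core — poorly perfused (low Ktrans, low f), freely diffusing (high
D0), T1w-hypointense, T2w-hyperintense — with adjacent-region separation of
at least 4 SD in every channel. Noise is Gaussian, not Rician, because the
clustering under test is distribution-agnostic; this and the i.i.d.
(spatially uncorrelated) draw are deliberate simplifications of MR noise.
Consequently, passing habitat-recovery tests demonstrate the pipeline's
correctness, not that real renal tumors separate this cleanly.

## Habitat analysis

Channels have incommensurate units (ms, min⁻¹, µm²/ms, s⁻¹), so features
are z-scored per channel within the tumor mask before k-means; profiles are
reported on raw units. k-means uses k-means++ with 10 restarts and an
explicit seed; local minima therefore never leak into results. Habitat
labels are renumbered by descending size with a lexicographic centroid
tie-break, making the labeling invariant to voxel and channel ordering.
Cluster-count selection maximizes the mean silhouette over k = 2..6 (ties
toward smaller k), computed on the full table up to 6,000 voxels and on a
seeded subsample beyond; a best silhouette below 0.2 raises a "no habitat
structure" flag. On the default three-habitat phantom at ≈ 5,000 tumor
voxels the selection returns k = 3 in essentially every seeded run.

## Problem sizes

The shipped study conditions are desk-scale by design: the default phantom
is a 103³ lattice at 1.5 mm; the mold grid is ≈ 1.9 M voxels at 1 mm; the
mold mesh starts near 380 k faces and is decimated to 20 k; the habitat
study uses ≈ 4,900 tumor voxels × 7 channels over 20 seeded trials.

## Known limitations

* The vertical-shadow cavity cannot reproduce overhanging recesses; a
  specimen with a strongly re-entrant lower surface would sit on its
  waterline, not its true surface.
* The roll objective weights both anchors equally; anchors nearly opposite
  in azimuth are balanced at mid-height rather than both reaching the base
  (and their 2-cm holes may then breach the walls, which is reported as an
  error rather than silently accepted).
* Specimen deformation after resection, fat trimming, and photograph-based
  coregistration of real sections are out of scope; the Dice reported here
  isolates mold geometry only.
* The slice-center anchoring of the slot plan is best-effort and only
  meaningful when the sectioning normal is close to an acquisition axis.
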