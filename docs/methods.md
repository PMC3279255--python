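# Methods

## Coding scheme

The projector coordinate along each axis is encoded twice.  A
reflected-binary Gray code over `2^L` stripes (default L = 8) gives a
coarse index whose neighbouring codewords differ in exactly one bit, so a
binarization error at a stripe boundary displaces the decoded index by at
most one stripe.  A phase-shift sequence of `line_width`-pixel lines
(default 1 px) sliding one pixel per frame over a `shift_period` (default
16 px) gives the coordinate residue modulo the period.  Decoding fuses the
two: the residue is kept and the Gray estimate selects the nearest
consistent period block, `c = s + P·round((coarse − s)/P)`.  A pixel is
rejected when no phase frame (or more than `line_width` frames) is lit,
when coarse and fine disagree by more than half a period, or when the
fused coordinate leaves the frame.  With the defaults the sequence is
2·8 + 2·16 = 48 frames, Gray before phase shift, horizontal before
vertical within each block; frame order is part of the format and stored
in every manifest.

Axes that are not divisible into `2^L` equal stripes (768 rows at L = 8)
get near-equal integer stripes via `idx = ⌊coord·2^L/size⌋`; widths then
differ by at most one pixel.

Binarization thresholds each pixel at the midpoint of per-session lit and
dark reference captures; pixels whose lit−dark contrast falls below
`contrast_floor` (default 5% of dynamic range) are unreliable —
background, or surface the projector cannot reach — and are excluded
before decoding.

## Camera model and calibration

All devices (reflectance camera, projector-as-inverse-camera,
fluorescence camera) are pinholes described by homogeneous 3×4 projection
matrices in a right-handed world frame: origin at the platform centre,
z up, millimetres.  Estimation is the normalized DLT (Hartley scaling on
both sides, SVD null vector, ≥6 non-coplanar correspondences); no lens
distortion terms.  Matrices are stored at unit Frobenius norm with the
sign fixed so the left 3×3 block has positive determinant, which makes
centres, optical axes and ray orientations unambiguous.  Camera
correspondences come from two perpendicular chessboards (8×10 and 7×11
squares, 26 mm pitch); projector correspondences from a projected 8×10
board of 50×50 px squares intersected with horizontal planes at 0, 500
and 1000 mm.

## Reconstruction

Per valid pixel, the camera ray and the decoded projector ray are
triangulated to the midpoint of their shortest connecting segment; the
segment length (ray gap) gates quality (`max_gap` 3 mm) together with a
positive-depth check on both devices.  Cleanup is the
radius-neighbour-count filter — a point survives with ≥ `min_neighbors`
(10) others within `filter_radius` (2.5 mm), counted in one pass on the
unfiltered cloud — followed by moving-least-squares smoothing: each point
is projected onto the total-least-squares plane of its 1.5 mm
neighbourhood.  The smoothing exists because decoded projector
coordinates are integers; the resulting sub-millimetre staircase jitter
lies along the camera rays and would otherwise inflate mesh area.  It is
unbiased wherever the surface is planar at the neighbourhood scale and is
disabled by setting the radius to 0.

Single-view meshing is 2-D Delaunay over the points' source pixels lifted
to 3-D — the image plane is a fold-free parameterization of a single
camera's range data — with triangles pruned when any 3-D edge exceeds
`max_edge` (5 mm, the same scale as the isolation criterion) or when
degenerate.  The two platform views are merged by rotating the second
cloud back about the vertical axis (no iterative registration; the
rotation is known).  A merged cloud has no single image plane, so labelled
regions (leaves) are re-meshed one by one in their own fitted-plane
parameterization; this also collapses surfaces sampled by both views into
one sheet so area is not double-counted.  Region labels come from the
synthetic ground truth or from user annotation — automatic leaf instance
segmentation is out of scope.

## Traits

Area is the summed triangle area (reported in cm²); height is the highest
vertex minus the configured pot height.  Leaf planes are total-least-
squares fits (smallest principal component, normal oriented upward).
Inclination is the angle between the plane and a reference axis in
[0°, 90°]: against the default vertical axis a horizontal leaf reads 90°
and a vertical leaf 0°; a camera-axis reference is available behind a flag
since both conventions appear in practice.  The dihedral angle between
two planes is signed by the right-hand rotation about the hinge axis
(their intersection line, or an explicitly supplied physical rotation
axis) and folded into [−90°, 90°] because fitted normals carry no
intrinsic sign.

## Fluorescence

Rfd₁₀₀ = (Fp − Fs)/Fs is computed per pixel or per vertex; entries with
Fs ≤ 0 are flagged undefined (NaN), not errors.  Vertices are projected
through the fluorescence-camera matrix and sampled bilinearly; a vertex is
invisible when it projects outside the frame, lies behind the camera, or
its line of sight to the camera centre is blocked by the mesh (ray-cast
occlusion test).  Under near-isotropic excitation a surface element
inclined by φ to the optical axis is imaged as S/cos φ, amplifying the
per-pixel signal by 1/cos φ; the correction multiplies per-vertex values
by cos φ using mesh normals oriented toward the camera.  The correction
assumes the isotropic regime and can be disabled for the anisotropic
camera-side-illumination case where the cosine factors already cancel.
Note that Rfd, a same-geometry ratio, is itself immune to the
amplification; the correction matters for Fp and Fs individually.
Distance effects are not corrected because imaged-surface growth and flux
decay both scale with distance² in opposite directions and cancel.
Whole-plant summaries are area-weighted over triangles whose three
vertices are visible (triangle value = vertex mean), with an equal-band
vertical profile to expose gradients such as stress appearing first in
top leaves.  Per-vertex averaging before ratio formation is the default;
the alternative order (average frames, then ratio) is a one-line variant
the summary exposes implicitly through the per-vertex fields.

## The virtual rig

Geometry follows the physical system: projector 1330 mm from the platform
centre at 30° from vertical (so 1152 mm above the platform), native
1024×768; reflectance camera on a stand 450 mm from the rotation axis at
600 mm height; fluorescence camera 512×512 on the arch; all aimed at
(0, 0, 80) mm; plant rotated 0°/180° on the platform.  Quantities the
publication-level description leaves open were fixed once as rig
engineering: the camera stand sits at 90° azimuth from the projector,
because triangulation conditioning degrades as the rays become parallel
(the perpendicular placement yields a ≈52° intersection angle at the
plant; a camera directly under the projector would be ill-conditioned);
focal lengths model a zoomed consumer camera (2.8× image width), a
throw-ratio-2 DLP (2.0×), and a 3.0× fluorescence camera.  The
reflectance camera's native 4416×3312 sensor is replaced by a
configurable stand-in (tests use 288×384–384×512) since the method is
resolution-agnostic.

Plants are vertical stems (two crossed, non-green 3 mm ribbons) carrying
planar elliptical leaf patches (24-triangle fans; the recorded truth is
the exact polygon area).  Leaves follow a phyllotactic spiral (golden
divergence ≈137.5° with ±10° jitter), carry 6–18 mm petiole offsets, and
tilt 20–50° from horizontal; the plant is shifted so the highest leaf
point sits exactly at the requested height above the pot.  A candidate
packing is accepted only when leaves keep ≥3 mm mutual clearance and
every leaf surface sample is jointly camera- and projector-visible, at a
non-grazing incidence, in at least one view.  This encodes the study
condition — healthy, turgid, non-overlapping foliage — and deliberately
excludes the wilted/overlapping case, which the physical validation also
identified as the method's failure mode.  Default emission yields are
Fp = 0.55 and Fs ≈ 0.25 of full scale per leaf (Rfd ≈ 1.2, the order
observed in healthy pepper).

Rendering casts one ray per camera pixel (vectorized Möller–Trumbore,
double-sided triangles) and records exact provenance: hit point, leaf id,
illuminating projector pixel (nearest-integer), projector shadowing.
Coded frames carry no Lambertian shading — binarization against
references is albedo- and shading-insensitive, so only lit level (0.85),
ambient (0.06), background (0.02) and Gaussian sensor noise (default σ =
1% of full scale) matter.  The fluorescence render instead carries the
1/cos φ amplification explicitly (per-leaf constant, since patches are
planar) with distance effects cancelling by construction.  All noise goes
through seeded generators; renders are byte-reproducible.

What the simulator does not emulate: leaf curvature and serration, veins
and albedo texture, projector defocus and gamma, interreflections,
mixed-coverage edge pixels (rays sample pixel centres), and the kinetic
fluorescence series (only Fp and Fs frames are produced).  Passing tests
therefore demonstrate the geometry and signal chain, not robustness to
those photometric effects.

## Numerical choices and problem sizes

Green threshold 20 (8-bit excess-green), contrast floor 5%, max ray gap
3 mm, isolation filter 2.5 mm/10 neighbours, smoothing radius 1.5 mm,
mesh edge limit 5 mm; all exposed in `PipelineConfig` (YAML, unknown keys
rejected).  Validation studies run at reduced stand-in resolutions chosen
for sub-minute module tests: area recovery uses 512×384 captures and five
or three plants, the dihedral sweep 384×288, single-leaf fixtures
288×384.  Closure evaluations of fluorescence sample a mesh shrunk 10%
toward the leaf centre so bilinear samples stay interior to the blade;
edge pixels of a real fluorescence frame mix leaf and background and
would need coverage weighting, which is not implemented.

## Known limitations

Integer-pixel decoding bounds depth precision at roughly half a projector
pixel divided by the sine of the ray intersection angle; sub-pixel line
localization would improve it but is not implemented.  The MLS smoothing
slightly flattens genuinely curved surfaces at the 1.5 mm scale.  Region
meshing assumes labelled regions are near-planar (true for the synthetic
leaves; curved real leaves would need a curved parameterization).  The
isolation filter is single-pass by design; iterating it to a fixed point
would remove additional points.  Two views leave residual occlusion on
dense canopies; the merge operation accepts any number of views, but the
packing criterion and validation studies use two.
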