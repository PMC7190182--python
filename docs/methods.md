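# Methods

This note documents the measurement model, the synthetic-data model, the
statistical model, and the numerical choices behind `sccmorph`.

## Anatomical frame and the nine parameters

All measurements are made in world millimetres in a RAS frame (+x right,
+y anterior, +z superior) after AC–PC reorientation: the midpoint of the
anterior/posterior-commissure segment is the origin, the AC–PC line is the
+y axis, the sagittal midline is the plane x = 0 and the axial plane is
z = const. The landmarks leave the roll about the AC–PC axis undetermined;
it is fixed by a "superior hint" vector (default: the input volume's +z).

Per side, nine parameters are measured:

| parameter | units | definition |
|---|---|---|
| `angle_lateral_superior`, `angle_superior_posterior`, `angle_lateral_posterior` | deg | angle between oriented best-fit canal plane normals, `arccos(n1 . n2)`, **not folded at 90°** |
| `lateral_inclination` | deg | angle between the lateral-canal plane and the axial plane, signed positive when the plane's anterior edge tilts superiorly |
| `midline_distance_lateral`, `midline_distance_posterior` | mm | horizontal distance from the midline to the canal's lateral-most aspect |
| `min_csa_lateral/superior/posterior` | mm² | minimum lumen cross-sectional area over the canal's divisions |

Normal orientation conventions resolve the ±n ambiguity of a fitted plane:
lateral normals point superiorly (n_z > 0); superior and posterior normals
point toward their own side (sign of n_x = side). Because plane angles are
not folded at 90°, values on either side of 90° are distinct — the folding
convention would otherwise erase exactly the kind of asymmetry the analysis
looks for. The inclination is invariant to flipping the stored normal.

## Segmentation

GrowCut is a synchronous cellular automaton on the voxel lattice
(26-neighbourhood). Each voxel carries a label and a strength in [0, 1];
neighbour q attacks voxel p with strength `g(|I_p − I_q|) · strength_q`,
`g(x) = 1 − x / range(I)`, and p adopts q's label when the attack strictly
exceeds p's strength. Seeds start at strength 1 and are never overwritten.
Seeding is systematic rather than interactive: foreground = voxels at or
above the 99.5th intensity percentile (T2 fluid is the brightest tissue),
background = the ROI border shell. Because the fixed point depends on the
seeds, segmentation runs twice: the first mask, eroded by one voxel,
re-seeds the foreground and the complement of its one-voxel dilation
re-seeds the background, letting the boundary re-compete.

The final surface is the marching-cubes iso-contour of the *intensity* at
the midpoint between the structure's median and the background's median
level, restricted to the (dilated) pass-2 mask. A binary-mask contour is
also available (`surface_from="mask"`), but on canals only 2–3 voxels wide
it carries a calibre bias and a several-percent cross-sectional wiggle; the
image itself encodes the boundary at sub-voxel precision through partial
volume, and contouring it removes most of that error. Connected components
below 100 voxels are discarded (configurable).

## Morphometry

An operator-style approximate centerline per canal (a polyline that extends
past the junctions) is resampled by arc length and the surface is cut
perpendicular to it every 0.25 mm (the *divisions*). Each division's
cross-section is the closed mesh-plane intersection loop whose centroid
lies nearest the path point; loop area and centroid come from segment-wise
shoelace sums with winding fixed by `plane_normal x face_normal`, so no
polygon ordering is needed. Sliver loops (< 0.05 mm², tangent grazes) are
rejected, as are loops whose centroid is farther than 2.5 mm from the path.

Canal endpoints are found by walking outward from mid-canal and stopping at
the first division whose area exceeds k x the canal median (default
k = 2.5) or whose centroid jumps discontinuously (the plane has latched
onto a neighbouring structure). Sliver divisions (< 0.35 x median) are
stripped from the segment ends, and the stored endpoint steps half a
division beyond the last interior centroid along the local axis — the
junction division's own centroid is dragged into the merged vestibule mass.
The superior and posterior canals' junction-side endpoints are snapped to
their midpoint, the single common-crus intersection point. The centroid
spline (cubic, arc-length resampled at the division spacing) is refined by
re-slicing perpendicular to itself (two passes by default) with a tightened
loop-acceptance radius of `max(1.5 spacings, 0.75 local radii)`; about one
tube radius at each end is pinned during refinement — junction mass would
otherwise drag the re-sliced end centroids outward and fold the spline on
every pass — and dropped afterwards. A self-intersection guard rejects
paths whose distant-in-arc samples approach within half a spacing.

**Plane fit.** The canal plane minimizes
`f(n, c) = sum_i | w_i n . (x_i − c) |^2` over unit normals, where x_i are
the canal's volumetric cloud points, `w_i = 1 / A_i^2` is the inverse
squared area of the nearest division, and c is the w²-weighted centroid of
the cloud. The normal is the smallest-eigenvalue eigenvector of
`sum w_i^2 (x_i − c)(x_i − c)^T`. Centring at the *weighted centroid* —
rather than at each point's nearest centerline sample — is essential: for a
tubular cloud the per-point displacement from the centerline has variance
~r²/4 along the plane normal but only ~(spacing/2)² along the local
tangent, so a nearest-point-centred objective is minimized by an in-plane
direction and the fit degenerates. With centroid centring the ring's radius
dominates the in-plane variance and the uniform-weight fit coincides
exactly with the classic total-least-squares plane.

Two conditioning steps protect the weights: the division-area profile is
median-filtered over 3 divisions (an isolated mis-measured sliver would
otherwise receive a divergent 1/A² weight and hijack the fit) and clamped
to [0.3, 3] x the canal median. When the source intensity volume is
available, cloud points additionally carry a partial-volume mass
`max(I − background, 0)`: a binary in/out voxel cloud of a thin tilted ring
imposes a grid-aliasing bias on the fitted normal that oscillates with tilt
(about ±1.3° at a 0.5 mm grid, period ≈ arcsin(voxel/ring diameter));
because the blurred image is a kernel-smoothed indicator, mass weighting
restores the true second moments and removes the bias.

**Minimum cross-sectional area** is the minimum of the division-area
profile strictly between the endpoints, after a 3-division running median
and a ~1.25 mm running mean: the meshed surface of a voxelized tube
wiggles, and a plain minimum over ~60 divisions is biased low by the
extreme-value effect. The window is short against anatomical area
variation, so smooth genuine minima are preserved (the window was
calibrated once against phantoms with constant and sinusoidal radius
profiles at two grid resolutions).

**Midline distance** is computed from the divisions: at each division the
tube surface extends `r_i sqrt(1 − t_x²)` beyond the centre in x (t = local
tangent, r from the division area, capped at 1.25 x the canal median
against junction inflation), and the endpoints contribute with the median
calibre. This is equivalent to the lateral-most surface point for circular
sections while keeping vestibule surface out of the estimate.

Subjects with a failed canal keep their remaining parameters (missing
values propagate; the mixed model tolerates incomplete sides).

## Statistics

Per parameter, the model is `value ~ group + side + group:side` with a
common unstructured 2x2 within-subject covariance over the right and left
measurements, fit by REML. For complete bilateral data this has a closed
form — cell means plus the pooled within-group sample covariance — and the
interaction test is *exactly* the pooled two-sample t-test on per-subject
R−L differences, which is the implementation's oracle. With missing sides
the covariance is estimated by numerical REML (log-Cholesky
parameterization, Nelder–Mead) with a fall back to the complete-case
difference t-test if the fit is singular. Confidence intervals use t
quantiles with n1 + n2 − 2 degrees of freedom, matching the
balanced-data equivalence. If every difference is zero the interaction is
reported as 0 with p = 1 (degenerate zero-variance case). Group-specific
covariances are not fit; age is not a covariate (canal geometry is fixed
at birth, so the groups' age difference is immaterial to these measures).

The nine nominal interaction p-values are corrected with the
**Benjamini–Liu step-down** procedure: with ordered p(1) ≤ … ≤ p(m),
`raw_j = min(1, (m−j+1)(1 − (1−p(j))^(m−j+1)) / m)` and the adjusted value
is the running maximum of raw over steps ≤ j, mapped back to input order
(stable ties). Unlike step-up procedures, the step-down adjusted value can
fall *below* the nominal p for large p (adjusted(1) = 1/m); the implemented
invariants are range [0, 1], monotonicity in sorted order and permutation
equivariance, verified against a grid inversion of the procedure's critical
values. Significance is declared at FDR q = 0.05.

Summary tables report group-by-side means and sample SDs (n−1; missing for
single-subject cells), per-curve-type mean R−L differences (controls form
one stratum; SD missing for n = 1), and Cobb-angle summaries per curve
pattern. Double-major (biphasic) curves list two angles per patient and
either aggregation is defensible, so both the all-angles and the
per-patient-maximum summaries are reported.

## Synthetic data

A phantom labyrinth is three planar circular arcs (≈270° of a torus each,
ring radius ~3 mm, lumen radius 0.6–0.8 mm) meeting a spherical vestibule
(default radius 3 x lumen radius); the superior and posterior rings also
pass through a common-crus blob placed on the intersection line of their
planes. This is the simplest geometry with every measured feature: canal
planes, lumen profile, junction endpoints and midline extent. Intensity
phantoms set each voxel to background + contrast x the fraction of the
voxel inside the lumen (analytic partial volume, linearized over one voxel)
plus Gaussian noise — emulating how MRI integrates sub-voxel anatomy; a
binarized label volume deliberately lacks that information and reproduces
the aliasing discussed above. Default noise SD is 5 % of the
lumen–background contrast; default grid 0.28 mm.

The cohort simulator draws per-subject, per-side parameter values from
bivariate normals with unstructured R/L covariance. Default means are
side-symmetric (so any interaction comes only from `interaction_delta`,
applied ±delta/2 to the AIS right/left lateral inclination) and the default
within-subject side correlation is 0.58, back-computed from published
control-group side SDs (3.88/3.03) and difference SD (3.25).

The end-to-end in-silico study (`sccmorph.pipeline.simulate_phantom_cohort`)
instead *builds and measures images*: each subject's labyrinth geometry
varies realistically (ring radius 3.0 ± 0.1 mm between subjects; lumen
radius 0.8 ± 0.03 mm between subjects and ± 0.03 mm between sides, as
published side SDs of minimum areas are large; labyrinth centre 39.5 ± 1.2
mm from the midline ± 0.8 mm per side; superior/posterior plane jitter
1.5°). The side's inclination (base 4.5°, 2.5° between subjects, 1.0°
between sides — per-side SD ≈ 2.7°, in the published 2–4° range, with the
strong bilateral correlation expected of paired anatomy) is applied as a
whole-labyrinth roll about +x, which changes the lateral inclination
exactly while leaving inter-canal angles, midline extents and areas
invariant — so a simulated "left-lateral horizontalization" contaminates no
other parameter. The study grid is 0.5 mm with 0.7 mm divisions and no
spline refinement, sized so that a full two-group study (39 subjects, both
sides, segmentation and measurement included) completes in a few seconds
per replicate; at this scale the per-side inclination measurement error is
approximately normal with SD ≈ 0.15° and no observed errors beyond 0.5°
across 240 sides.

What the phantoms do **not** model: real labyrinth anatomy (non-planar,
non-circular ducts, ampullae, utricle/saccule), MRI physics (bias fields,
anisotropic PSF, motion), and operator variability in placing the
approximate centerlines. Passing phantom tests therefore demonstrates the
correctness of the measurement chain on idealized tubular geometry, not
clinical accuracy on real images.

## Numerical choices and degenerate inputs

- Resampling preserves the voxel->world mapping exactly (output index k
  maps to input index k x spacing ratio); labels use nearest-neighbour.
- Perona–Malik smoothing uses 6-neighbour differences, conductance
  `exp(−(d/K)²)` with K = conductance x intensity range / 10, time step
  1/7 (≤ 1/6 required for 3D stability); off by default for labels.
- Plane fits require ≥ 4 points and reject collinear clouds (second
  eigenvalue < 1e-12 of the largest).
- Cross-section slicing perturbs vertices lying exactly on the plane by
  1e-9 to keep crossings generic; mesh-plane loops are grouped by shared
  crossed mesh edges via union-find.
- GrowCut convergence: sweeps stop when no voxel changes label (at most
  `max_iter` = 200); ties (attack equal to current strength) never
  overwrite, which also guarantees seed permanence.
- Reslicing skips divisions whose plane misses the mesh and fails if more
  than 20 % are skipped.
- Zero residual variance in the interaction model yields a degenerate
  CI of width zero and p = 1 when the estimate is 0.

## Limitations

- Canal labelling relies on the operator-supplied approximate paths; there
  is no automatic canal identification.
- Endpoint localization by the area-threshold rule is resolution- and
  threshold-dependent; on phantoms the detected endpoints sit within about
  one millimetre of the true junction mouths.
- The midline-distance estimate assumes near-circular cross-sections.
- The unstructured covariance is common to both groups; a group-specific
  covariance (with Welch–Satterthwaite degrees of freedom) is not
  implemented.
- The 0.5 mm in-silico study grid trades accuracy for throughput; absolute
  minimum-area values at that scale carry a systematic few-percent bias
  (identical across groups and sides, so contrasts are unaffected).
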