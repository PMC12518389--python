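# Methods

## Measurement model

The package treats implant loosening assessment as a rigid-motion
estimation problem. Two CT volumes of the same knee are acquired under
opposite bending moments (valgus and varus). Each object of interest — the
tibial implant and the tibial bone — is assumed rigid, so its pose change
between the scans is a 4×4 homogeneous matrix `T` with orthonormal,
determinant +1 rotation block. The clinically meaningful quantity is the
implant's motion *in the bone frame*,

    T_rel = T_bone⁻¹ · T_implant,

which removes the shared patient repositioning. `T_rel` is summarised by
its screw (helical) decomposition and by per-vertex displacements of the
implant surface mesh (rScrew, MTPM, mTRE; see README). All coordinates are
world millimetres; volumes are axis-aligned grids in which voxel *centers*
anchor the index→world map (`world = origin + index · spacing`).
Direction-cosine rotations in volume headers are rejected rather than
silently reinterpreted.

## Registration

Per object, registration composes two stages:

* **ICP initialisation** (implant only): nearest-neighbour correspondences
  between the valgus and varus implant mesh vertices, rigid update by
  orthogonal Procrustes (SVD), iterated until the mean correspondence
  distance change falls below 1e-6 mm or 50 iterations. The tibia has no
  second mesh and starts from identity; with only load-direction changes
  and table repositioning between scans the bone displacement stays well
  inside the optimizer's capture range.
* **Point-to-image refinement**: the double contour carries the grey
  values sampled in the valgus scan at ±0.3 mm along the outward vertex
  normals (trilinear interpolation; out-of-bounds sample points are
  dropped, never clamped). The objective is the Pearson correlation
  between these reference values (inner and outer concatenated) and the
  values sampled in the varus scan at the transformed point locations.
  Pearson correlation is invariant to positive affine intensity rescaling,
  so global brightness/contrast differences between scans do not move the
  optimum. The search space is 3 translations (mm) + 3 intrinsic XYZ Euler
  rotations (deg) about the contour centroid — centering the rotation at
  the centroid largely decorrelates rotations from translations for the
  optimizer. Nelder–Mead with the classic coefficients (reflection 1,
  expansion 2, contraction 0.5, shrink 0.5), initial simplex steps
  1 mm / 1°, stops when the simplex objective spread falls below 1e-6 or
  after 500 iterations, then restarts once from the optimum with steps/10.
  Candidates pushing more than 20 % of the contour out of the target
  volume score correlation −1. The returned transform never scores below
  the initial one, and a final correlation under 0.5 flags the result as
  non-converged (reported, never silently accepted).

All contour points are the mesh vertices themselves; an optional uniform
subsampling exists for speed but is off by default.

## Screw-axis kinematics

The rotation angle comes from `atan2(‖skew(R)‖/2, (tr R − 1)/2)`, which
stays accurate where plain `acos` loses precision. The axis direction
comes from the skew-symmetric part; within 1° of 180° it switches to the
dominant column of `R + Rᵀ + (1 − tr R)·I`, avoiding the catastrophic
cancellation of the skew part. The slide is the translation component
along the axis and the axis point solves the helical equation
`(I − R)c = t_⊥` in closed form, `c = ½(t_⊥ + (d × t_⊥)/tan(θ/2))`.
Below 1e-7° the motion is treated as a pure slide (direction from the
translation, or ẑ for identity). Rebuilding the matrix from the four screw
parameters reproduces the input to < 1e-9, and the angle matches a
quaternion half-angle computation to < 1e-9 deg (tested on 10⁴ random
transforms). MTPM/mTRE use *all* implant-mesh vertices; no marker subsets.

## Segmentation and metrics

Region growing returns the connected component (default 26-connectivity)
of the thresholded volume containing the seed. Largest-component filtering
breaks size ties by the smallest linear voxel index. The margin carve
dilates the implant mask with a spherical element of per-axis radius
`ceil(radius/spacing)` voxels (default radius 3 mm) and removes the
overlapping bone; it never adds voxels and never touches the implant mask.
Dice of two empty masks is defined as 1. HD95 is the 95th percentile
(linear interpolation) of the *pooled* symmetric nearest-neighbour
distances between surface voxels (voxels with a 6-neighbour outside the
mask) — HD95 variants differ across tools, so the pooled definition is
fixed here. Surface meshes come from marching cubes on the binary
indicator at iso 0.5 (one-voxel zero padding keeps boundary-touching masks
closed); vertex normals are area-weighted face normals, oriented outward
by probing the mask interior. Note that marching cubes on binary data
carries a known positive surface-area metrication bias (~9 % for a
sphere, independent of resolution); vertex *positions* are still accurate
to within half a voxel diagonal.

## Phantom design

The phantom exists to give every downstream stage a ground truth. The
scene is a tapered, elliptical-cross-section bone (cortical shell +
trabecular interior) and a plate-plus-stem implant, both defined by exact
signed-distance functions in their own frames. Volume 1 renders the scene
at identity; volume 2 renders the bone at the global repositioning `G` and
the implant at `G·S`, where `S` is the configured screw motion — so the
ground-truth implant-relative-to-bone transform is exactly `S`. Rendering
is always analytic at each pose; no volume is ever produced by resampling
another, so interpolation artefacts cannot masquerade as method error.

Design choices that matter:

* **Soft edges.** Intensities are tissue means weighted by an erf profile
  of the signed distance (`edge_sigma_mm`, default 0.3 mm ≈ ⅔ voxel),
  emulating the finite PSF of a CT reconstruction. This is deliberate: on
  infinitely sharp binary renderings the correlation optimum is biased by
  voxel aliasing at the ~0.2° level — an artefact of the simulation, not
  of the method — whereas real CT data are band-limited. `edge_sigma_mm=0`
  gives the hard phantom used by voxel-exact segmentation oracles. Labels
  always come from hard voxel-center occupancy (signed distance ≤ 0).
* **Elliptical bone** (aspect 0.75). A circular bone makes rotation about
  its own long axis invisible to any intensity-based method; real tibiae
  are azimuthally asymmetric.
* **Carved margin.** The bone solid excludes a 2 mm neighbourhood of the
  implant at its volume-1 pose, keeping the solids disjoint (as the
  post-processed masks of the real workflow are) and making the truth
  transform well-defined for motions smaller than the margin; larger
  configured motions raise a geometry error rather than rendering an
  impossible scene.
* **Degradations.** Additive Gaussian noise (default SD 10 HU-like units,
  a plausible bone-kernel CT noise level) and an optional fixed-pattern
  radial streak field centred on the implant (default amplitude 0; no
  quantitative artefact model is available, so severity is a config knob).
  An optional Gaussian partial-volume blur is off by default.
* **Scale.** Default grid 128³ at 0.45 mm isotropic (≈ 5.8 cm cube), which
  renders in a few seconds and registers in tens of seconds on one CPU.
  The test suite uses a geometrically scaled 64³ variant for unit tests
  and the 128³ default for end-to-end recovery and null-error checks; the
  small fixture's implant has less rotational leverage, so its unit-test
  recovery tolerance is 0.2° instead of the full-scale 0.05°.

What the phantom does *not* emulate: beam hardening, photon statistics,
reconstruction kernels, implant brand geometry, bone microstructure, or
segmentation errors of real anatomy. Passing recovery tests therefore
demonstrates correctness of the measurement chain on clean rigid scenes,
not clinical accuracy.

## Statistics

* **Wilcoxon signed-rank**: zero differences dropped before ranking, ties
  mid-ranked (the classic treatment; conventions differ between tools).
  Exact mode enumerates all 2ⁿ sign assignments (n ≤ 15 after zero
  removal) and reports `2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))` capped at 1; larger n
  uses the normal approximation with continuity and tie correction. Ten
  all-positive differences give 2/1024 ≈ 0.00195, reported as 0.002.
* **Mann–Whitney U**: exact mode enumerates all rank subsets for
  n₁+n₂ ≤ 12; otherwise the tie-corrected asymptotic test.
* **Bootstrap median CI**: percentile method (not BCa), R = 1000 default,
  seeded generator for determinism.
* **ICC(A,1)**: two-way model, absolute agreement, single measurement,
  from ANOVA mean squares
  `(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, with the
  McGraw–Wong F-based 95 % CI. Identical columns return ICC 1 with a
  degenerate CI; zero total variance is an error.
* **Multiplicity**: Bonferroni `α/m`; report helper rounds to 3 decimals
  (0.05/6 → 0.008, 0.05/24 → 0.002). Labels: `ns` for p ≥ 0.05, `*` for
  α_corr ≤ p < 0.05, `**` for p < α_corr.

## Pipeline conventions

Mask-supplied mode is the default interface (external DL segmentations
drop in as ordinary label files); region-grow mode reproduces the
semi-automatic arm on phantoms. The implant is registered before the
tibia. Every run can write its transforms, meshes, heatmap PLY, outcome
JSON and a machine-readable log with per-stage timings and convergence
flags. Batch runs record per-pair failures in the results table and
continue; group summaries use the seeded bootstrap and Mann–Whitney tests.

## Known limitations

* The tibia receives no ICP initialisation; very large table repositioning
  (beyond a few mm / a few degrees) could exceed the simplex capture range
  and would need a manual or mesh-based bone init.
* Euler-angle parameterisation assumes the small-angle regime typical of
  loaded-knee pose changes; it is not suitable for arbitrary large
  rotations.
* HD95 and Dice operate on shared-geometry grids only; no resampling
  between mismatched grids is provided.
* The phantom's streak model is a stand-in; robustness numbers under real
  metal artefacts cannot be claimed from it.
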