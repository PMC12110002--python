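# Methods

## Problem setting

After implantation of a directional deep-brain-stimulation (dDBS) electrode,
the segmented contacts that steer the stimulation field are visible only in
a high-resolution, narrow-field-of-view cone-beam CT acquired
postoperatively, while the stimulation target (the subthalamic nucleus) is
visible only on the preoperative T2-weighted MRI. Programming the device
from images therefore requires fusing the two volumes. The two modalities
share very little anatomy — bone and electrode are conspicuous in the CT
volume, soft tissue in the MR volume — which rules out fully automatic
registration from an arbitrary start and motivates the semi-automated
protocol implemented here:

1. **Centered initialization** — superimpose the two FOV centers
   (identity rotation).
2. **Landmark-based rigid fit** — a closed-form least-squares fit to three
   or more corresponding points picked on structures visible in both
   modalities (in practice the semicircular canals, which are fluid-bright
   on T2 and embedded in conspicuous petrous bone on CT).
3. **Mutual-information refinement** — single-resolution gradient descent
   on a stochastically sampled Mattes mutual-information metric.
4. **Evaluation** — target registration error (TRE) on a second, held-out
   landmark set, before and after refinement.
5. **Visualization** — electrode-oriented multiplanar reformation (MPR) with
   window/level mapping and alpha blending.

## Geometry and conventions

All physical quantities are millimetres in the LPS frame (DICOM/ITK
convention); NIfTI files (RAS world) and 3DSlicer fiducial files (RAS by
default) are sign-flipped on the first two axes at the I/O boundary. Voxel
centers sit at integer 0-based indices; the voxel-to-world map is
`p = origin + direction @ (spacing * idx)` with an orthonormal,
determinant-+1 direction matrix. When a NIfTI header carries both a qform
and an sform, the sform wins; the float32 header storage is compensated by
re-orthonormalizing the direction matrix (polar decomposition) on read.

Rigid transforms are parameterized by a unit quaternion (versor), a
translation, and an explicit fixed rotation center, and map fixed-space
points to moving-space points: `q = R (p - c) + c + t`. The center is set to
the fixed image's physical centroid (centered initializer) or the fixed
landmarks' centroid (landmark fit), which decouples the rotation parameters
from large translations during optimization. Euler-angle conversion uses
ZYX intrinsic order (`R = Rz Ry Rx`). Only the 6 parameters
(3 versor vector components, 3 translations) are optimized; the center is
held fixed.

The landmark fit solves `argmin_T Σ ||T(f_i) - m_i||²` by SVD of the
cross-covariance (Kabsch) with a determinant guard that forbids
reflections. Pairing is by file order, with a warning when label names
disagree. Collinearity is detected when the second singular value of the
centered fixed points falls below 1e-9 of the largest; planar
configurations (any n = 3 triplet) remain valid because the reflection
guard makes the proper-rotation solution unique.

## The Mattes mutual-information metric

The metric is the negative mutual information (natural log, nats) between
fixed-image intensities at a random subsample of fixed voxel centers and
moving-image intensities trilinearly interpolated at their transformed
positions. Following the standard Mattes construction, fixed intensities
enter the joint histogram with zero-order (box) windows and moving
intensities are spread over four neighbouring bins with a cubic B-spline
Parzen window, making the metric smooth in the transform parameters. Bin
ranges span each channel's sample minimum..maximum, with the top edge
folded into the last bin; both channels use the same bin count (default
50, the conventional choice). A box+box mode exists solely so tests can
compare the value against an independent brute-force joint-histogram MI
(they agree to 1e-12; with identical inputs the value reduces to the
plug-in entropy of the binned image).

Two sampling decisions matter and are deliberate:

- **The sample is drawn once per registration** (seeded, uniform without
  replacement, `ceil(fraction × N_voxels)` points with the protocol default
  fraction 0.01) and reused across iterations. This makes every run
  bit-reproducible; re-drawing per iteration would only add gradient noise.
- **Samples are confined to the overlap region at the initial transform**
  (fixed voxels whose mapped position lies inside the moving volume, eroded
  by a 2-voxel margin). The plug-in MI estimator has a positive
  small-sample bias that grows as the in-bounds sample count shrinks; with
  unrestricted sampling over a full-FOV fixed image against a narrow-FOV
  moving image, the optimizer is rewarded for pushing samples out of
  bounds and the metric optimum drifts off the true alignment. Restricting
  the sampling region — the standard fixed-image-mask practice — keeps the
  effective count constant across iterations and removes this artifact.
  Samples that still map out of bounds during optimization are dropped from
  the histogram (no boundary padding); the per-iteration overlap fraction
  is logged.

## Optimization

Plain gradient descent for at most 30 iterations (protocol default), with
the gradient computed by central finite differences on the 6 parameters
(default physical step 0.2 mm; versor steps are divided by the lever arm —
the distance from the rotation center to the farthest fixed-domain corner —
so rotation and translation components are commensurate in millimetres).
The step length is rescaled every iteration so that the maximum
displacement induced on the fixed-domain corner points equals
`learning_rate × coarsest voxel spacing` (default 0.33 × 1 mm), i.e. a
normalized, physically calibrated step. Convergence is declared when the
metric varies by less than `convergence_min` (default 0.01 nats) over a
10-iteration window (the window length is a documented constant). The
returned transform is the best-metric point visited, including the start,
so refinement can never report something worse than its initialization.
Shrink factor and smoothing sigma default to 1 and 0 mm (single
resolution) and are pass-through parameters only.

## Evaluation

TRE_i = ||T(fixed_i) - moving_i||₂ in mm on the evaluation landmarks, with
the arithmetic mean and the *sample* standard deviation (n-1 denominator —
the denominator choice is declared because it matters at n = 3). Evaluation
landmarks must be disjoint from initialization landmarks; overlap triggers
a warning. Reports serialize to JSON and CSV.

## Electrode-oriented MPR

The electrode axis is the normalized vector between two user-supplied
contact coordinates (no automatic electrode detection). Because "a plane
oriented by the electrode" is ambiguous, both view families are provided:
`inplane` (the plane contains the axis — long-axis views of the lead) and
`orthogonal` (plane perpendicular to the axis — contact cross-sections).
The in-plane basis tie-break is deterministic: `u = normalize(axis × ẑ)`,
falling back to `x̂` when the axis is within ~2.5° of `ẑ`. Slices are
single-plane trilinear samplings (no slab averaging); the pixel-to-mm map
is exact and exported alongside every image. Fusion windows each slice
(window/level, clipped to [0, 1], applied after extraction) and
alpha-blends them.

## Synthetic phantom

No patient data ships with the package; every stage is exercised on a
synthetic two-modality phantom with a known ground-truth transform. One
anatomical scene — ellipsoidal head with a skull shell, two bilateral
canal-like tori embedded in petrous-bone-like blocks, a midline
ventricle-like CSF slab, a low-contrast nucleus-like ellipsoid, and an
electrode (bright line with three contact blobs) — is rendered twice:

- **CT-like** on a fine narrow-FOV grid (default 128³ @ 0.4 mm) in moved
  space: bone, canals and electrode hyperdense; soft tissue flat.
- **MR-like** on a coarse full-FOV grid (default 96³ @ 1.0 mm) in fixed
  space: soft-tissue contrast, bright canals and CSF, dark bone,
  hypointense nucleus, no electrode (preoperative).

The default grids are desk-scale stand-ins that preserve the clinical 1:5
fine-to-coarse spacing ratio (the clinical regime, 512×512×497 @ 0.2 mm vs
192×192×160 @ 1 mm, is available behind `full_size_spec` / `--full-size`).
The two intensity mappings are non-monotone in one another by construction
(bone: bright CT / dark MR; CSF: flat CT / bright MR), verified as a rank
correlation |ρ| < 0.5 of paired in-FOV intensities — so correlation-based
metrics cannot align the pair while mutual information can, reproducing
the clinical motivation for an MI metric. Structure edges use a compactly
supported cubic smoothstep (±0.8 mm band): an infinite-tail profile would
imprint a monotone distance-to-bone trace on every soft-tissue voxel that
is invisible in intensity but dominates rank statistics.

The ground-truth transform is drawn per seed (rotation axis and angle
uniform up to 5°, translation up to 5 mm by default — the regime of head
repositioning between imaging sessions); the fine FOV is centered on the
scene as seen in moved space and must be strictly contained in the coarse
FOV. Landmarks are exact scene coordinates: canal apices for
initialization (four points, two per side), and three held-out evaluation
points (nucleus center, a posterior canal apex, a contralateral
soft-tissue point). Gaussian noise is added per modality (SD 40 for the
CT-like volume against a 100–4000 intensity range, SD 25 for the MR-like
volume against 100–1000; chosen once as plausible relative noise levels).
A degradation mode truncates one canal at the FOV edge — the known failure
mode of narrow-FOV acquisitions — and displaces the corresponding landmark
pick by 1.5 mm, emulating the placement inaccuracy an incomplete
reconstruction causes.

What the phantom does *not* model: CT beam hardening and cone-beam
peripheral distortion, MR field-inhomogeneity warping, motion artifacts,
postsurgical anatomy change, and real tissue texture. Passing tests
therefore demonstrate the correctness of the geometry, metric, optimizer
and pipeline plumbing under the stated noise model — not clinical accuracy
on real data.

## Benchmark protocol and problem sizes

`run_phantom_trial` generates one subject, degrades the landmark-fit
initialization with an isotropic Gaussian translation offset of 1 mm RMS
(emulating imperfect manual picks; without it the exact synthetic
landmarks make the initialization perfect and leave nothing to refine),
runs the refinement, and scores pre/post TRE on the held-out landmarks.
The standard benchmark is 20 seeded trials at the default phantom scale;
the test suite additionally uses a coarser variant (64³ @ 0.8 mm / 48³ @
2 mm, same physical FOVs) where per-test speed matters. On the default
scale, refinement reduces the mean TRE in ≥ 19/20 trials with a median
post-refinement TRE of ~0.1–0.5 mm (below the coarse voxel size), as
recomputed by `scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Trilinear interpolation via `scipy.ndimage.map_coordinates`; continuous
  indices within 1e-9 voxel of an integer are snapped so grid-aligned
  resampling is bit-exact.
- Out-of-bounds resampling fill defaults to 0; exposed as a parameter.
- Constant intensity in either metric channel returns MI = 0 with a
  warning; fewer than 2 in-bounds samples is an error advising landmark
  initialization.
- Versor parameter updates guard ‖v‖ < 1; the scalar part is kept
  non-negative (canonical sign).
- Window/level requires window > 0; alpha blending requires a shared grid
  and alpha in [0, 1].

## Known limitations

- Rigid-only; no affine or deformable models, so modality-dependent
  geometric distortion is absorbed into the TRE rather than corrected.
- Single-resolution refinement with a fixed-length physical step: the
  final accuracy is limited to roughly one step (0.33 × coarse voxel), and
  the capture range is small by design — the method counts on a good
  landmark initialization.
- The stochastic metric makes the refined transform depend on the sampling
  seed; determinism is per-seed, not seed-free.
- No automatic landmark or electrode detection; both are user inputs.
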