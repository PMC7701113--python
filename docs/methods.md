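# Methods

`msemap` measures the system-dependent geometric distortion of an MR scanner
over a field of view larger than its distortion phantom, by stitching scans
of the phantom acquired at several patient-table positions.  This note
records the model, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## The displacement model

A fiducial sphere whose designed position (phantom design mapped through a
rigid placement estimate) is `x_d` appears in the image at `x`; its
displacement observation is `d = x - x_d`, attached to the *apparent*
coordinate `x`.  Pooling all scans ("series" `s`), the model is

    d(x, s) = delta_s + eps_s × x + D(x)

where `delta_s` (mm) and `eps_s` (rad, linearized rotation about the scanner
origin) absorb the phantom placement error of series `s`, and `D` is the
scanner's distortion field, shared by all series because it is a property of
the scanner, not of where the phantom sat.  `D` is expanded in tensor
products of Chebyshev polynomials of the second kind,
`U_m(x~) U_n(y~) U_p(z~)` per displacement component, over box-normalized
coordinates `x~ ∈ [-1, 1]`.

The constant and linear terms of the raw tensor expansion span the rigid
motions.  They are reparameterized exactly into 3 translations and 3
antisymmetric rotations — both excluded from `D`, since they are the
per-series rigid parameters — plus 6 symmetric strain terms
(`xx, yy, zz, xy, xz, yz`), which are genuine distortion and are retained,
built directly in physical mm so that they contain no constant part.  The
distortion block of the design matrix is therefore: 6 strain columns + all
tensor terms with `2 ≤ m+n+p ≤ cap`, per component.

After the joint fit the per-series rigid parameters are discarded; `D` alone
is the distortion map.  The centre series — the one scan placed at isocenter
by the patient-alignment lasers — is the exception: its `(delta, eps)` is
the measured misalignment between the laser system and the scanner's
gradient frame (including any centre-frequency translation), returned by
`laser_misalignment` as a proper rigid transform via the matrix exponential.

### Gauge freedom

A globally rigid component of the true field is indistinguishable from
phantom placement: the method recovers `D` only modulo one global rigid
field.  Concretely, the split between "rigid" and "distortion" depends on
the normalization box, because a Chebyshev term over one box expands with
constant/linear parts over another.  Consequences honoured throughout the
package:

- construct-and-recover is exact (< 1e-9 mm) only when truth and fit share a
  `BasisSpec`; with an independently chosen basis the recovered-minus-truth
  difference is itself one global rigid field (`remove_rigid_component`
  subtracts it for comparisons);
- two independently fitted fields (e.g. single-scan vs stitched) are
  compared over a common basis box, or after de-gauging.

### Order selection and regularization

Per-axis polynomial order = the number of distinct fiducial planes along
that axis in the centre scan (planes found by splitting sorted coordinate
gaps at their largest multiplicative jump; this presumes grid-like designs).
The cap on `m+n+p` is `floor(1.5 × max order)`.  This deliberately
over-parameterizes — with `k` planes, order `k` has `k+1` degrees of freedom
— so the unregularized system is singular on an exact grid, and Tikhonov
regularization does the real model selection: the penalty is
`lambda ||W A||^2` with diagonal weights `w = 1 + (m+n+p)^2` (strain counts
as order 1), applied **only** to distortion coefficients, never to the rigid
blocks.  `lambda` defaults to the minimizer of generalized cross-validation
over `10^-8 … 10^2`.

Solver: columns are scaled to unit norm; GCV is evaluated on the
rigid-partialled problem through one SVD (exact, because the rigid columns
carry no penalty); the final solution is an augmented least squares with
penalty rows, which remains accurate down to `lambda ≈ 1e-10` where a
ridge-via-SVD formulation leaks field energy into the rigid blocks through
near-degenerate directions.  Because the per-series translation columns are
orthogonal to nothing but themselves, translating one series' designed frame
changes only that series' `delta`, to ~1e-12 — the computational content of
"no absolute phantom position needed".

## Segmentation

Spheres are dark in a bright background liquid.  Detection per sphere
diameter: (1) a template is generated mathematically from the diameter on a
5×-per-axis oversampled grid (125 subsamples per voxel) and volume-averaged
to the native anisotropic voxel size, so template edges carry the same
partial-volume profile as the image; (2) zero-normalized cross-correlation
of template and image, computed via FFT correlation and sliding-window sums
(identical to direct NCC to < 1e-10; the half-template border, where the
window does not fit, is blanked); (3) local maxima above an NCC threshold
(default 0.5) accepted greedily in descending score with a millimetre
exclusion radius (default 15 mm, specified in mm because voxels are
anisotropic); (4) sub-voxel refinement: an 11³ neighbourhood of the peak,
tapered with a flat-centre Tukey window, is sinc-interpolated (Fourier
zero-padding) by 8× per axis, and a 3-point parabola per axis on the
upsampled surface interpolates below the 1/8-voxel grid.  Numerical notes:
the 11³ crop matters (a 9³ crop truncates the correlation peak of a 10 mm
sphere at 1.5625 mm voxels and biases the estimate by ~0.06 mm); the
sub-grid parabola is required for the ~0.01 mm noiseless accuracy that makes
a null session read < 0.05 mm.

Partial-volume model (shared by template and renderer): each voxel is split
into 5³ subcells; within a subcell the sphere surface is treated as a plane
perpendicular to the local radial direction, whose box-overlap fraction is
an exact linear ramp in signed distance.  Exact for planar cuts; curvature
error is second order (≤ 0.003 against Monte-Carlo integration at 10 mm
spheres).

## Localization

The three landmark spheres have enlarged diameter (15 vs 10 mm) and sit at
the vertices of a scalene triangle whose pairwise side differences are
≥ 5 mm, so side-length ordering identifies each vertex uniquely.  Candidate
detections are those scoring within 0.15 of the best NCC in the
large-template pass (the enlarged spheres outscore ordinary ones decisively;
this also prevents ambiguity with grid triples congruent to the landmark
triangle); every 3-subset is scored by the sum of absolute sorted-side
differences, with failure above 3 mm and an ambiguity error if two distinct
triples agree within 1 mm.  The placement is the orthogonal Procrustes
(Kabsch) transform of the three matched pairs, determinant +1 enforced.
Designed-to-detected correspondence is mutual-nearest-neighbour within
10 mm — below half the 30–40 mm sphere spacing, above the few-mm distortion
— which makes matching one-to-one and order-independent.  Landmark-based
placement is approximate (the landmarks sit in a distorted image); the error
is an almost-rigid motion absorbed by the per-series rigid terms.

## Synthetic scans

The renderer places each sphere at its apparent position — the fixed point
`a = t + D(a)`, consistent with the apparent-coordinate convention, so that
point correction is a single subtraction — and draws it with the shared
partial-volume edge model; sphere shapes are not warped (shape distortion is
second order at few-mm field magnitudes over ≥ 10 mm spheres).  The default
session emulates the study conditions: 505 spheres (10/15 mm) in a
350 × 270 × 200 mm cloud (an 11 × 9 × 7 grid thinned to the 505 centre-most
points with ~1 mm jitter, so it is grid-like but not a lattice), voxels
1.5625 × 1.5625 × 1 mm in a 243 × 192 × 240 volume, table shifts
(0, +50, −50) mm along z with each volume centred on the phantom, Gaussian
noise of 2 % of background (Rician available), and random placement
perturbations ≤ 0.5 mm / 0.2°.  One scan covers 200 mm in z; three scans
extend the measurement to 300 mm.

`simulate_observations` is the fast fiducial-level path (no images).  Its
`small_angle=True` mode applies the placement perturbation in the same
linearized form the fit uses, enabling exact construct-and-recover; with
exact rotations the per-series symmetric `O(theta^2)` remainder
(~3e-3 mm at 0.3°) is not representable by the shared strain block and sets
the recovery floor — itself asserted as the linearization property.

What the synthetic data does **not** emulate: susceptibility and chemical
shift (patient-induced distortion), sequence-dependent contrast, intensity
bias fields, 2D multi-slice geometry, and vendor-correction residue
structure.  Passing tests therefore demonstrate the estimator's correctness
and stability under the stated geometry and noise, not scanner-specific
distortion magnitudes — those are measurements of a physical scanner.

## Correction and validation

Point correction: `corrected = x - D(x)` (exact under the apparent
convention).  Image correction solves `x - D(x) = y` per output voxel by
fixed-point iteration (`x_0 = y + D(y)`, tolerance 0.01 mm, ≤ 10 iterations,
divergence reported with its location), sampling the input by trilinear
interpolation; the displacement is pre-evaluated on the voxel grid by a
separable tensor contraction and interpolated during iteration (the field is
smooth at the ~1 mm scale of a voxel).  Fill value 0 outside the source, with
a validity mask.

Validation statistics: boxplot summaries of |d| per 20 mm radial bin from
the isocenter (type-7 linear-interpolation quartiles — chosen and fixed so
oracle tests are exact — Tukey whiskers clipped to the data range, empty
bins reported); and inter-sphere distance comparison over all
`n(n+1)/2 − n` pairs, which is invariant to rigid motion of either set and
therefore needs no phantom pose.  The isocenter defaults to the scanner
world origin and is configurable.

## Problem sizes used in the shipped experiments

Rendered full sessions use the 505-sphere design at 243 × 192 × 240 voxels
× 3 scans; focused experiments (field recovery, gauge, laser misalignment)
run at fiducial level on the same design; the correction round trip and
overlap-consistency experiments use 120–210-sphere designs in
160 × 144 × 176-voxel volumes.  These sizes were chosen so the complete
synthetic study, including rendering and two full fits, runs in minutes on a
single core while preserving the study geometry.

## Known limitations

- The distortion field is estimated only where fiducials sample it;
  polynomial extrapolation beyond the stitched phantom envelope is flagged
  but not validated.
- The order-selection heuristic assumes grid-like designs; for irregular
  clouds, set `orders` explicitly.
- The laser-misalignment readout inherits the gauge convention: it is
  meaningful relative to the nominal (laser-aligned) placement used to form
  the designed positions.
- The fit weights all observations equally; NCC-score weighting is not
  implemented.
- `correct_image` assumes `|grad D| << 1`, amply true at few-mm fields over
  hundreds of mm; it will abort with a divergence error otherwise.
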