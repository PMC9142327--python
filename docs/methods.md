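# Methods

## Model

A tooth's movement between two scan timepoints is modelled as a rigid
displacement **m** = A **n** + **o**, with A ∈ SO(3) and **o** in mm. The
assumptions behind that choice: a crown is rigid over clinical intervals
(no wear or restoration between scans), the cast and scanning chain add
only small, roughly isotropic-per-axis errors, and the reference
structure used for normalisation genuinely does not move relative to the
skull between timepoints. Violations (a moving "stable" reference,
non-rigid cast distortion) bias every downstream number and are not
detectable from within the data; the calibration-plane check bounds only
the scanner's contribution.

Every rigid displacement equals a rotation θ about a unique line (the
finite helical axis, direction **h**, point **q**) plus a translation
*t* along it (Chasles). The decomposition used here is the
finite-displacement form, computed from (A, **o**) of a single interval;
instantaneous helical axes from velocity data, and smoothing/
cross-validated estimators, are out of scope.

### Axis extraction

Points on the axis are exactly those whose displacement
**p**(**n**) = (A − K)**n** + **o** is parallel to the axis, equivalently
invariant under the rotation, **p** = Aᵀ**p**. Substituting gives the
linear system (A + Aᵀ − 2K)**n** + (K − Aᵀ)**o** = 0, which is rank 2 for
0 < θ < 180° with the axis line as solution set; the same points minimise
‖**p**‖.

Two solution strategies are implemented:

* **minimum_norm** (default): rank-2-truncated SVD solve, giving the
  axis point closest to the origin. The truncation is explicit rather
  than tolerance-based because the system's third singular value is a
  numerical zero whose inclusion would leak an arbitrary (and
  arbitrarily large) component along the axis into the solution.
* **fix_coordinate**: zero one coordinate and solve the remaining 2×2
  system. Fixing a *prescribed* coordinate fails whenever the axis is
  nearly perpendicular to it, so the implementation fixes the coordinate
  with the largest |**h**| component. Both strategies return points on
  the same line (verified to sine < 1e−8 in tests).

The axis direction is the unit eigenvector of A with eigenvalue 1, read
from the skew part of A with the right-hand-rule sign; at θ > 179.99° the
skew part vanishes and the dominant eigenvector of (A + K)/2 is used with
the first-nonzero-component-positive sign convention (irrelevant at
dental scales, required for totality). The rotation angle is the trace
identity θ = arccos(clamp((tr A − 1)/2)), clamped against floating-point
drift at 0° and 180°; a geometric cross-check (project a probe point and
its translation-stripped image onto the axis, measure the subtended
angle via atan2) agrees to 1e−8° and is part of the test contract. The
screw translation is **p**(**q**)·**h** for any on-axis **q**.

Angles are degrees and lengths millimetres at every public interface;
radians appear only inside computations.

### Degeneracy

Below `degeneracy_threshold` (default **0.1°** — well under the ~0.8°
smallest rotations one expects to report) the axis position is undefined
and the motion is encoded as a pure translation (**h** = **o**/‖**o**‖,
*t* = ‖**o**‖, axis point NaN), never an exception. Between 0.1° and
**0.5°** the decomposition is computed but flagged `unreliable`: under
fixed noise the axis-position error grows steeply as θ shrinks (the
acceptance suite measures a ~80× median error ratio between 0.2° and 5°).

## Registration

The Kabsch fit (SVD of the cross-covariance of centred, corresponded
clouds, smallest-singular-direction sign flip so det A = +1) is the inner
solver. Configurations whose centred source has a relatively tiny second
singular value (< 1e−9) are rejected as collinear/coincident rather than
silently returning an unconstrained rotation.

ICP is point-to-point with *exact* nearest-neighbour correspondence
(k-d tree; ties resolved deterministically) alternated with Kabsch on the
kept pairs; optional distance-trimming (`trim_fraction`) drops the
farthest pairs for partial-overlap robustness. Initialisation is the
identity: serial casts scanned in one apparatus are coarsely pre-aligned,
and the simulator's pose perturbations (≤ 5°, ≤ 5 mm) stay comfortably
inside the convergence basin for these blob-like structures. There is no
global-registration fallback, no point-to-plane variant, and no use of
mesh normals. Defaults: `max_iter=100`, `tol=1e−6` mm improvement,
`trim_fraction=0` in the library (the CLI's `register`/`axis` commands
default to 0.1).

The fitting-error statistic is the mean nearest-neighbour distance from
the source to the target cloud — asymmetric by definition, which matches
its use (each tooth point to its closest counterpart on the later scan);
a symmetric average is available via a flag. It is computed over all of a
structure's labelled points.

Series normalisation ICP-registers each scan's reference-labelled subset
onto the first scan's and applies the transform to the whole scan. The
normalizing transforms are returned so raw-frame results can be
reconstructed by composition. Per-tooth interval transforms are computed
on the normalised clouds.

## Calibration plane

"Least squares" for a plane is ambiguous between regressing z on (x, y)
and minimising geometric distances; the deviation metric is geometric, so
the default is orthogonal (total) least squares — centroid plus smallest
principal direction — with the z-regression variant exposed for
comparison (it can only be worse in RMS geometric deviation, which a test
asserts on tilted clouds). Deviations are signed point-to-plane
distances; the accuracy statistic takes the maximum of their absolute
values. Normal sign convention: positive z-component, else first
non-zero component positive.

## Synthetic data generator

The generator emulates the measurement chain of a five-timepoint serial
cast study:

* **Crowns** are superellipsoid surfaces (exponent 0.8; half-axes
  4×3×5 mm by default) sampled by casting seeded random directions from
  the centre onto the implicit surface — quasi-uniform for these mildly
  aspherical shapes, and exactly on the surface, which gives a
  closed-form oracle. Anatomical realism (cusps, fissures, undercuts) is
  explicitly not modelled.
* **The arch** places three anterior "teeth" plus a bilateral posterior
  molar pair sharing one reference label (the stand-in for first molars
  splinted by a transpalatal bar), ~40 mm across.
* **Motions**: per-tooth screw motions per consecutive interval, drawn at
  the scale such studies report — rotations 0.5–5°, translations
  0.05–0.5 mm, axes within 20 mm of the arch — accumulate in the
  anatomical frame; the reference structure never moves.
* **Cast placement**: each scan after the first gets a random whole-scan
  pose (rotation uniform in [0, 5]°, translation magnitude uniform in
  [0, 5] mm), which normalisation must remove.
* **Noise**: the scanner's stated axis resolutions (0.01 / 0.1 / 0.01 mm)
  are quantisation steps, not Gaussian widths, so the default noise is
  Gaussian with σ = step/√12 per axis (variance-matching a uniform
  quantiser ≈ (0.003, 0.029, 0.003) mm); a pure-quantisation mode
  (`quantize_cloud`) is also provided. No noise model is published for
  this class of scanner — this is the package's own assumption.

All randomness fans out from one seed through CRC-32-hashed child seeds
keyed by (seed, operation, label, timepoint), so regeneration is
bit-identical and independent of call order.

What passing tests on this generator do **not** show: robustness to
segmentation errors at the gingival margin, partial crown overlap between
timepoints, occlusion blind spots from the three-orientation scan merge,
or non-rigid cast distortion. Trimmed ICP addresses partial overlap
mechanically but is untested against realistic dropout patterns.

## Problem sizes and determinism

The test and acceptance workloads use 1000 random screws for the
decomposition contracts, 50 instances (≤ 12 points) against the
exhaustive axis-angle grid oracle (2° grid with Nelder-Mead refinement),
a 5000-point crown for the ICP contract, 10⁴ points for the plane fit,
100 noise replicates per condition for the sensitivity ordering, and
700-point teeth in the five-timepoint pipeline — sizes at which every
targeted tolerance is meaningful while the whole suite runs in seconds.
Hypothesis-based property tests are derandomised.

## Known limitations

* Point-to-point ICP assumes comparable sampling of the two clouds; large
  density mismatch biases the nearest-neighbour error downward for the
  sparser source.
* With measurement noise the per-iteration ICP objective is guaranteed
  non-increasing only under the fixed correspondence/trim policy; the
  reported final error is recomputed untrimmed over all points and can
  exceed the last trimmed objective value.
* The fix-coordinate axis-point variant is kept for fidelity to manual
  computation practice; minimum-norm is better conditioned and is the
  default everywhere.
* Screw parameters of rotations within ~0.1° of 180° have a sign-
  ambiguous axis; at dental scales (≤ 10°) this never occurs.
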