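# Methods

## Coordinate conventions

All geometry lives on the sagittal plane through the treatment isocenter,
in millimetres: `a` is the AP coordinate (anterior positive), `s` the SI
coordinate (superior positive). Shift vectors follow the clinical sign
convention — positive LR/SI/AP means left/superior/anterior. LR is
carried through the data model but excluded from modelling: after bone
registration, lateral target motion is sub-half-millimetre noise, and the
generator produces it as exactly that.

## The synthetic-anatomy generator

Each patient gets a baseline anatomy drawn once: bladder, rectum,
prostate and CTV as smooth star-convex polygons (superellipses, 64
vertices) and the pubic bone as a convex quadrilateral whose
superior-posterior and inferior-posterior corners are the landmarks S
and I. Sizes and positions are drawn uniformly from ranges chosen to
mimic mid-sagittal pelvic anatomy at the isocenter level; the rectum sits
directly posterior to the prostate with a gap of a few millimetres, as in
real anatomy, which matters for the registration comparator (its region
of interest, CTV + 5 mm, must genuinely sample the rectal wall).

Each fraction draws an unobserved state `(u, v, w)` from independent
standard normals: upper-rectal filling, lower-rectal filling, bladder
filling. These drive

* the rectal anterior wall: displaced anteriorly by `k_u·u` at the S
  level and `k_v·v` at the I level (linear interpolation in between,
  tapered by how anterior a vertex sits so the flanks stay put); the
  posterior wall follows half of that plus an independent disturbance
  `k_r·r` so that wall position and diameter are correlated but not
  collinear;
* the bladder: scaled about its centroid by `1 + 0.05·w` and jittered by
  1 mm;
* the target: prostate and CTV translate rigidly by the true shift

  ```
  si = α_u·u + α_w·w + ε_si          α = (1.0, 0.4),  ε ~ N(0, 0.3 mm)
  ap = β_u·u + β_v·v + β_w·w + ε_ap  β = (1.4, 0.6, 0.4)
  ```

  and that translation is recorded exactly as the reference shift.

The couplings are calibrated so pooled cohorts show mean |SI| ≈ 0.9 mm
and mean |AP| ≈ 1.3 mm (the day-to-day scale reported for bone-registered
prostate cohorts), the SI and AP shifts are positively correlated (the
anterior-superior / posterior-inferior diagonal along which the target is
known to travel), and the upper-rectal-wall feature f3 is the strongest —
and negative — correlate of both components.

Measurement noise: every measured wall point gets i.i.d. Gaussian "click
noise" (SD 0.5 mm per coordinate) emulating manual caliper placement by
different professionals. The prostate-center point carries its own,
larger noise (SD 2 mm): judging the middle of a low-contrast gland on
CBCT is far less reproducible than clicking a crisp wall, and without
this distinction the center-point features f8/f9 would be near-perfect
proxies of the (rigidly translated) target and would implausibly dominate
the correlation ranking.

Rectal gas is modelled as an elliptical pocket hugging the upper anterior
rectal wall, present in a fraction (default 25%) of pretreatment images.
The pocket is an intensity-only overlay: it never moves the wall
contours, so the measured distances — and any feature-based prediction —
are provably identical with and without it.

What the generator does *not* emulate: 3D anatomy and out-of-plane
motion, CTV rotation and deformation, realistic HU values and CBCT
artifacts, intrafraction motion, and physically consistent organ contact
(at extreme rectal filling the deformed wall may overlap the CTV contour;
rasterization resolves this by paint order). Passing tests therefore show
that the measurement, learning and evaluation machinery is correct and
well calibrated — not that the specific accuracy numbers transfer to
patients.

## Feature measurement

S maximizes `s − a` over bone vertices, I maximizes `−s − a` (ties:
more superior / more inferior, then more posterior). Distances follow the
caliper definitions: d1 is the Euclidean distance from S to the bladder's
most-posterior boundary point (tie broken toward superior — the "top" of
the posterior convexity; an AP-projected variant would differ only by the
small SI component and is not exposed); d2 the SI distance from S to the
bladder's superior wall on the vertical line through S; d3/d5 the AP
distances from S/I to the rectal anterior wall on the horizontal lines
through them; d4/d6 the rectal AP spans on those lines; d7 = d6 − d4.
Intersections are computed against polygon edges; if a line crosses the
boundary more than twice (non-convex wall), the outermost pair defines
the wall and diameter. A missing required intersection raises an error
naming the distance — never a silent NaN. A wall lying on the wrong side
of its landmark is likewise an error, not a negative distance.

The feature vector is `f_l = d_l(pretreatment) − d_l(planning)` for
l = 1…7 plus the prostate-center offsets f8 (SI) and f9 (AP),
pretreatment minus planning. f7 is recomputed as `f6 − f4` so the
identity holds to the last bit; the feature matrix is rank-deficient by
construction, which is a property of the feature set, not a defect to
repair. All distances are bone-relative, so a rigid translation of an
entire anatomy changes nothing.

## Regressors

All five architectures fit one shift component each; SI and AP get
separate models.

* **ANNs** — one hidden layer (tanh), linear output, 4–10 hidden nodes.
  Inputs and targets are z-scored on the training fold. Trainers:
  Levenberg–Marquardt (damping μ₀ = 0.001, ×10 on rejection, ÷10 on
  acceptance), Bayesian regularization inside LM (μ₀ = 0.005; objective
  `β·Ed + α·Ew` with the evidence re-estimation of α, β from the
  effective number of parameters each accepted epoch), and Møller's
  scaled conjugate gradient (initial λ = 5·10⁻⁷, σ = 5·10⁻⁵). Stopping:
  1000 epochs, gradient ∞-norm below 10⁻⁷, or (LM/BR) damping overflow.
  No early-stopping validation split — BR supplies the regularization.
  Initialization is seeded; training is deterministic given the seed.
* **SVR** — RBF kernel, ε-insensitive loss. `C = IQR(y)/1.349`, the
  robust estimate of the target scale (fallback C = 1 with a warning if
  the IQR is zero). ε and C are in mm: targets are *not* standardized for
  SVR so that the ε grid {0.01 … 1.0} keeps its physical meaning; inputs
  are z-scored and γ = 1/p on the standardized inputs. Dual tolerance
  10⁻⁶.
* **RF** — bootstrap per tree, ⌈p/3⌉ features per split, minimum five
  samples per leaf, seeded.

Hyperparameter selection scans one parameter at a time over the fixed
grids (hidden nodes 4–10; ε ∈ {0.01, 0.05, 0.1, 0.3, 0.5, 1.0}; trees ∈
{10, 30, 50, 70, 100, 150}) minimizing mean absolute *training* error,
ties to the smallest value.

Order dependence: SVR solves a convex problem and is row-order invariant
to solver tolerance; forests resample rows by index, so reordering the
training set changes individual trees while the fitted function stays
close — the leak check is therefore exact for SVR and functional for RF.

## Evaluation

Leave-one-patient-out cross-validation holds out all fractions of one
patient; features are re-ranked inside each training fold by default so
no information from the held-out patient enters the subset choice (a
pooled-ranking variant is available via `rank_per_fold=False`). Residuals
are absolute differences per direction; summaries report mean ± sample SD
(n−1; configurable) and max per direction and pooled over SI and AP.

Statistics: Spearman ρ uses average ranks and an exact permutation
p-value for n ≤ 9 (t approximation above). The Steel–Dwass all-pairs
comparison ranks each pair jointly and refers the tie-corrected
standardized rank sum to the studentized-range distribution with k groups
and infinite df; with exactly two small untied groups it returns the
exact rank-sum p, since the procedure then *is* the rank-sum test. The
variance F-test is two-sided (`2·min(cdf, sf)`). Cohen's κ discretizes
shifts to 1 mm bins centered on integers (width configurable) — the
binning is a choice, stated here because κ depends on it. Dice overlap
uses exact polygon clipping.

The grey-value comparator rasterizes anatomies at 1 mm pixels (organs as
distinct constant intensities, gas lowest) and exhaustively searches
integer-pixel translations maximizing the correlation ratio of
intensities within the CTV + 5 mm region, ties toward the smallest
|shift|, followed by per-axis parabolic sub-pixel refinement (skipped
when the integer match is already perfect, so exact self-matches are
recovered exactly). The gas-sensitivity experiment pairs, per seed, the
same pretreatment anatomies registered with and without a pocket and
averages three fractions per seed — one fraction leaves too many exact
ties from the integer search for a sign test to resolve.

## Problem sizes and determinism

Default cohorts follow the study layout: 10 training patients × 38
fractions and 10 validation patients × 10 fractions. The test suite runs
the cross-validation criteria at that scale and the statistical
calibrations at 2000 null replicates; the comparator experiments use 50
seeded trials. All randomness flows from explicit integer seeds through
`numpy` generators; identical seeds give bit-identical cohorts, models
and reports (the pipeline report embeds the config digest and seed, and
deleting intermediates and re-running reproduces identical bytes).
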