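# Methods

## Arch model and assumptions

The anterior arch (distal canine contact to distal canine contact, through
the incisal point) is modelled as a third-degree parabola, mirrored at the
raphe median plane to give a U-shape. The choice of a cubic rests on
anatomical–morphological grounds: it is the established low-order polynomial
for the *anterior* segment specifically; alternative families (beta
functions, catenaries, Fourier series, higher-degree polynomials) describe
the full arch and are out of scope here.

The model assumes:

- the arch is symmetric about the raphe median plane (per-side computations
  relax this: each side is evaluated with its own depth and width);
- the incisal point is the vertex of the parabola; the inter-canine line is
  the x-axis;
- treatment moves the incisal point sagittally (projected onto the occlusal
  plane); vertical displacement Δv is reported for bite-change bookkeeping
  but does not feed back into the arch-length integral, because the arch
  model lives in the occlusal-plane projection.

With depth *L* ≥ 0 and half-width *W* > 0 (mm), the one-sided arc length is
∫₀^W √(1 + 9L²/W⁶·x⁴) dx, and the full length is exactly twice that. L = 0
is admitted as the degenerate straight arch; it makes the identity
AL = aaw exact and provides the natural boundary for collapse-to-straight
treatment plans.

Useful structural facts, all enforced by tests: 2·√(W²+L²) ≤ AL ≤ 2·(W+L);
AL is strictly increasing in L at fixed width; AL(cL, c·aaw) = c·AL(L, aaw)
(the integrand depends only on L/W, so the model is scale covariant).

## Cephalometric conversion

Tipping about the centre of rotation (radius *c*, mm) enters through the
literal trigonometric formulas (see `archlen.cephalometrics`); angles are
degrees at the interface, radians internally. Two conventions are fixed and
documented rather than guessed:

- `delta_inclination` = (angle at T1) − (angle at T0). The upper-jaw formula
  contains a double negative, so its cosine argument *gains* the inclination
  change; at typical configurations (∢1/NL ≈ 110°, ∢OcP/NL ≈ 10°) a positive
  change therefore yields a *negative* Δs. The library applies the formula
  literally and does not flip signs silently.
- Angle conversions between ∢1/NL, ∢1/NSL, ∢1/NA, ∢1/ML, ∢1/NB use the
  standard additive plane identities (∢1/NSL = ∢1/NL − ∢NL/NSL,
  ∢1/NA = ∢1/NSL − SNA, ∢1/NB = ∢1/ML + ∢ML/NSL + SNB − 180°), under the
  assumption that paired angles open to the same side; an
  `opening_direction` flag flips the plane-offset sign for the opposite
  configuration. Over-determined inputs are cross-checked to 0.5° and
  rejected if inconsistent.

Occlusal-plane sensitivity substitutes each candidate OcP angle into the
tipping formula with everything else fixed and reports the max–min spread of
the predicted AL_T1. The default grid is integer degrees over the user's
range; no interpolation. At a representative protrusion configuration
(c = 22 mm, ∢1/NL = 110°, +5°, L = 14 mm, aaw = 36.2 mm) a 6° OcP range
moves AL_T1 by under 0.1 mm — OcP misidentification is clinically
negligible for this model.

## Numerical choices

- Arc length: adaptive Gauss–Kronrod quadrature (`scipy.integrate.quad`)
  with absolute and relative tolerance 1e−9. The integrand is smooth and
  monotone on [0, W]; no singular handling is needed. 1e−9 mm is far beyond
  the 0.1 mm precision at which results are clinically read. Tests verify
  agreement with an independent composite-Simpson oracle (10⁴ subintervals)
  to a relative 1e−6 on a 20×20 grid of L ∈ [0, 25], aaw ∈ [20, 45] mm.
- A zero-change prediction reuses the same code path as the baseline
  calculation, so AL_T1 equals AL_T0 bitwise.
- Degenerate inputs: W ≤ 0 and L < 0 raise immediately at construction;
  treatment plans that would drive L below 0 or aaw to 0 raise an error
  naming the offending post-treatment quantity.
- Evaluating the profile outside [0, W] requires an explicit
  `allow_extrapolation=True` (plotting convenience), so out-of-domain values
  cannot slip through validation.
- Per-side vs total bookkeeping: per-side lengths use that side's own L and
  W (one-sided integral); the total uses the mean of the two depths and the
  summed width, L_total = (L_left + L_right)/2, aaw = W_left + W_right.
  Because the total model is symmetric while the two sides generally are
  not, a small discrepancy (≈0.3 % at realistic asymmetry) between the
  summed per-side lengths and the total-model length is inherent to this
  bookkeeping, and visible in the validation statistics even at zero noise.

## Synthetic cohorts: what they emulate and what they do not

No cast data ships with the package. `generate_cohort` draws per-patient,
per-jaw, per-side arch dimensions from truncated normal distributions whose
mean/SD/min/max defaults reproduce the descriptive statistics of a treated
orthodontic cohort (N = 50, fixed appliances, both jaws, pre- and
post-treatment); truncation is by rejection so no new distributional
assumptions enter beyond the printed ranges. Left and right values of one
arch are drawn with correlation 0.7 — the sides of one jaw are anatomically
coupled; the value is a design choice exposed on `CohortSpec`, not an
empirical estimate. Post-treatment geometry is drawn independently from the
post-treatment strata rather than by simulating treatment; end-to-end
prediction tests instead apply explicit `ArchChange` plans.

Measurement emulation follows the cast procedure: the arch is approximated
from the inside by a polyline through reference points on the curve (13
points / 12 subsections in routine use; deterministic equal-x spacing by
default, a seeded uniform-random mode matching manual point placement).
Chord sums underestimate the arc; the error decays as O(n⁻²) in the number
of subsections (log–log slope verified in [−2.3, −1.7]) and is ≈0.01 % at 12
subsections on a typical arch — measured-vs-ideal-approximation deviations
reported for hand-drawn arches (≈0.5 %) are dominated by manual point
placement, which this emulation does not reproduce.

Measurement noise is additive zero-mean Gaussian with one SD for every
measured quantity (L, W, and the polyline-derived AL), default 0.2 mm. This
default places simulated intra-rater reliability in the excellent range
(ICC > 0.9) and yields mean concordance between measured and calculated AL
of ≈0.98 at n = 50 — the same qualitative regime as real-cast validation
studies. What passing these tests shows is that the pipeline is
self-consistent under realistic dimension distributions and measurement
noise; it does not show that a real arch is a cubic parabola, that raters
place points without bias, or that projection/calibration errors of the
photographic procedure are negligible.

## Agreement statistics

- Lin's CCC uses population (n-denominator) moments per its original
  definition; its confidence interval uses the Fisher z-transform with
  se = 1/√(n−2). CCC of two constant equal series is undefined and raises.
- ICC: the two-way, absolute-agreement, single-measure form ICC(A,1) is the
  default — the appropriate choice for repeated measurements by one rater —
  computed from the standard mean-square decomposition; the consistency form
  is available, and the variant is recorded in the report. Degenerate
  matrices may yield ICC ≤ 0 and are reported as computed, never clamped.
- Bland–Altman differences are oriented measured − calculated; limits of
  agreement are mean ± 1.96·SD (normal 95 %, not t-adjusted), standard
  practice for agreement plots.
- Absolute-difference summaries (mean, SD, min, max, 95 % t-CI) quantify the
  clinically interpretable disagreement in mm, complementing the abstract
  coefficients. Interpretation scales (Fleiss for ICC; Koch & Spörl for CCC)
  are attached as labels only.

## Known limitations

- The model covers the anterior segment only; nothing is claimed about the
  arch posterior to the canines.
- The centre-of-rotation distance *c* is an input; estimating it from
  moment-to-force ratios is out of scope.
- Angle-conversion identities assume consistent 2-D projections of the
  reference planes; unusual opening configurations need the
  `opening_direction` flag set by the user.
- The synthetic generator reproduces marginal per-stratum distributions and
  a fixed side-to-side correlation, not the full joint distribution of real
  arches (e.g. depth–width correlation within a side is not modelled).
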