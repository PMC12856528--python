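# Methods

## The measurement model

A central sulcus (CS) depth profile is a vector of 101 depth values (mm) at
equidistant relative positions 0 (medial) … 100 (lateral) along the
parametrized sulcus.  Raw parametrization output stores depth as positive
ridge-to-fundus length; the analysis convention inverts it so profiles start
near 0 and run negative.  Inversion is an explicit, idempotence-guarded
pipeline step so the sign convention of any intermediate table is always
auditable.

## Smoothing

Each inverted profile is low-pass filtered with a natural cubic smoothing
spline, knots at all 101 grid positions.  Writing the penalized criterion as
‖y − f‖² + λ·∫f″², the fitted values at the knots are ŷ = (I + λK)⁻¹y with
the Reinsch penalty K = DᵀC⁻¹D (D the second-difference matrix, C the
tridiagonal Gram matrix of the unit-spaced grid).  Rather than fixing λ, the
smoother is calibrated by its **effective degrees of freedom**: λ is solved
by bisection on log λ so that trace((I + λK)⁻¹) = 20 within 1e−3.  On the
fixed grid this costs one cached eigendecomposition of K; both the solve and
each smoothing reduce to an O(n²) matrix product (λ ≈ 12.4 on the 101-point
grid).

Choosing the trace criterion over generalized cross validation is a
deliberate design decision: a stated target of 20 degrees of freedom
uniquely determines λ, whereas GCV would choose a different λ per profile
and ignore the target.  The fit agrees with R's `smooth.spline(df = 20,
all.knots = TRUE)` to ~1e−4 (the tolerance of R's own df solver) and with
`scipy.interpolate.make_smoothing_spline` at the same λ to 1e−9; both
cross-checks are part of the test suite.  Constants and straight lines lie
in the penalty null space and pass through unchanged.

## Turnpoints and density clustering

Turnpoints are interior strict sign changes of the first differences.  Runs
of equal values (plateaus) collapse to a single extremum at the run
midpoint, with half-positions rounded toward the medial end — a
deterministic tie-break matching the medial→lateral scan order.  Maxima and
minima alternate by construction and the deepest minimum is flagged as the
global minimum (equal depths break medially).  The detector is verified
against a brute-force nearest-unequal-neighbour oracle on all
first-difference sign patterns up to length 8 and on 10⁴ random profiles.

Pooled extrema are summarized by a product-Gaussian 2D KDE on a 100 × 100
grid spanning the outermost extrema.  Per-axis kernel sds follow the
normal-reference rule in the conventional full-width form
4·1.06·min(sd, IQR/1.34)·n^(−1/5), divided by 4 — numerically identical
(≤ 5e−10, tested against `MASS::kde2d`) to the classic implementation whose
density magnitudes (~10⁻³–10⁻²) the summary levels assume.  The default
summary level is 0.0025; `density_summary` reports the peak cell and the
bounding box of all cells at or above the level.  An explicit bandwidth
override (`h`, full-width semantics) exists for sensitivity analyses; the
test suite uses it to check mode recovery on a known Gaussian, where a wider
kernel stabilizes the grid peak without biasing it.

## Landmark extraction

* **PPfpm-II** (lateral end): the deepest local minimum at positions
  strictly greater than 45.  If no local minimum lies lateral of the
  threshold, the deepest grid point lateral of it is used and flagged —
  this makes the landmark total, mirroring its reported universality.
  Equal-depth candidates resolve to the most medial position.  A
  whole-profile global minimum at or medial of the threshold raises
  `global_min_medial_of_threshold`; `ppfpm2_not_deepest` records profiles
  where the landmark is not the profile's deepest point.
* **PPfpm-I** (peak): the local maximum with the largest position strictly
  medial of PPfpm-II — in double-elevation profiles deliberately the
  *adjacent*, not the highest, maximum.  Absent when no maximum lies medial
  of PPfpm-II.

Extraction operates on the smoothed profile; raw-profile extraction is
available by passing an unsmoothed profile's turnpoints explicitly.  Extent
metrics require both landmarks; with PPfpm-I absent they are explicit
missing values, never zeros.

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with
per-profile ground truth, so every downstream stage is testable.  A profile
is built in the inverted convention as **base + elevations + noise**:

* **Base**: a shape-preserving (PCHIP) spline through anchor points.
  Profiles carrying a PPfpm elevation use a "plateau" base — a decline to a
  deep mid-section about 1.5 mm above the trough, a short accentuated drop,
  the trough, then a steep lateral incline.  Unimodal profiles instead
  decline steeply all the way to the trough, which both reproduces that
  shape class's sharp medial incline and suppresses spurious noise-induced
  maxima.  Medial and lateral end depths default to −2 and −4 mm.
* **Elevations**: Gaussian bumps per shape class — none (unimodal), one
  (bimodal), one plus a separated medial elevation (trimodal), or a split
  pair of sub-peaks (double elevation).  The configured "height" is the
  intended landmark difference y_II − y_I; the Gaussian amplitude is that
  height minus the base's own elevation at the apex.  Bump width scales
  with height (σ = 2.6·h^0.5), which — together with the apex-position
  spread — induces the positive height–width correlation (r ≈ 0.5 at the
  defaults) without a hand-coded dependence.
* **Noise**: a sum of 3–5 random cosine components with frequencies up to 6
  cycles per profile, scaled to 0.5 mm SD.  The perturbation is smooth by
  design: it exercises, rather than overwhelms, the spline smoothing.

Calibration targets are the published cohort statistics: trough position
N(60.79, 5.12) truncated to (45, 80], trough depth N(−23.78, 1.60) mm, apex
position N(45.77, 6.12), height N(4.53, 2.70) truncated at 0.02 mm, shape
mix 8/70/15/7 % (unimodal/bimodal/trimodal/double).  Three construction
details keep the *extracted* statistics on those targets: the trough anchor
alone is deepened by the bump tail's lift so the realized lateral minimum
stays on the drawn depth; and two small selection-bias compensations (0.50
mm depth, 0.40 positions lateral) offset the expected displacement of a
noisy valley minimum.  Subject-level draws carry 70 % of each trait's
variance, hemisphere-level jitter the rest, giving within-subject
correlation for the paired analyses.

Covariate effects are additive and centred so population means stay on
target: males 1.0 mm deeper overall; right hemispheres shifted 1.8 positions
lateral (trough and apex) with the PPfpm-I depth offset of −0.82 mm applied
through a reduced bump height, keeping PPfpm-II depth hemisphere-stable.
The Oldfield handedness index is drawn on the −100…100 grid (step 5) with
8.6 % left-handers, 0.7 % zeros, and right-handers skewed toward +100.

**Ground truth** is defined by applying the landmark rules to the
constructed (noisy, pre-smoothing) curve.  Recovery tests therefore measure
exactly the footprint of the smoothing stage; at the defaults the pipeline
recovers the lateral minimum within ±1 position for ~98 % and the apex
within ±2 positions for ~97 % of bimodal profiles at least 2 mm high.

What the generator does **not** emulate: mesh-level anatomy, superficial
CS-discontinuing variants, the right-skew of the height distribution (a
truncated normal is a declared simplification), medial global minima at the
empirical 4 % rate (the synthetic rate is < 1 %), or any spatial correlation
with external anatomy.  Passing tests therefore show the *pipeline* is
correct and well-calibrated under these study conditions, not that it would
be robust to real-data artifacts such as parametrization failures.

## Statistics battery

The three-way mixed ANOVA (two 2-level within factors, one 2-level between
factor) is computed from per-subject contrast scores: the subject mean, the
two within-factor contrasts, and their interaction.  Each score is regressed
on the sum-to-zero-coded between factor; the intercept test is the within
main effect (the *unweighted* grand mean of group means — what makes the
decomposition type-3 under an unbalanced between factor, as with the
unbalanced sex variable), the slope test its interaction, the subject-mean
stratum the between-factor test.  All effects are F(1, N−2).  The
implementation matches a direct sums-of-squares decomposition to 1e−10 on
balanced designs, squared sum-coded OLS t statistics on unbalanced ones, and
holds its 0.05-level size within the binomial interval over 1000 null
simulations.

Post hoc paired t-tests are classical two-sided tests with 95 % CIs and a
Bonferroni threshold α/m (0.0125 for the four standard comparisons).
Zero-variance differences return the mean difference with an undefined t,
flagged.

Handedness, with its heavy class imbalance, gets a threefold treatment:

1. **Balanced mirrored resampling** — per iteration every left-hander
   (index v) is matched to a right-hander with index −v, sampled uniformly
   without replacement; when no exact mirror remains the nearest available
   index is used (ties toward the smaller index), counted as a warning.
   The ANOVA runs on each balanced set; per-effect medians of F and p are
   reported over the iterations (default 10 000), with no combination rule
   beyond the median.
2. **Permutation** — between-factor labels permuted at subject level with
   group sizes preserved; empirical p = (b+1)/(m+1) with b the count of
   permuted F ≥ observed, never exactly zero.
3. **Random-intercept LMM** — REML fit (via statsmodels MixedLM) of the
   full feature × hemisphere × handedness factorial with a per-subject
   random intercept; t = β/SE is reported without denominator degrees of
   freedom, as is conventional for this model family.  Boundary fits
   (intercept variance → 0) are returned flagged, not raised.

Both resampling procedures are reproducible from (seed, iterations).
Assumption checks (Shapiro–Wilk per group; Levene centred on the mean across
the sex × hemisphere cross) are informational and never gate an analysis.

## Numerical and edge-case choices

* df solve: bisection on log λ over [e⁻²⁵, e³⁵], tolerance 1e−3 on the
  trace; targets outside (2, 101) are configuration errors.
* Smoothed profiles are clamped at 0 (the cortical surface) — the spline
  may overshoot the ridge line by a numerically meaningless amount.
* Plateau tie-breaks, equal-depth minima, and adjacent-maximum selection
  are all deterministic and medial-preferring.
* ANOVA strata with zero residual variance return F = 0 when the effect sum
  of squares is zero and +inf otherwise.
* The LMM fit falls back from gradient to derivative-free optimizers when
  the information matrix is singular on small unbalanced designs.
* Pipeline stages that cannot run (no complete feature pairs, a single
  between-factor level, too few handedness classes) are skipped with a
  manifest notice, never silently.

## Problem sizes

Tests and the acceptance script use 500-subject synthetic cohorts (1000
profiles) for calibration and recovery, 1000 replicates of a 16-subject
design for ANOVA null calibration, m = 10 000 permutations for the
permutation floor and 2000 for the separated-groups check, and 200 subjects
for LMM parameter recovery.  These sizes give stable Monte-Carlo estimates
while keeping a full test run in the low minutes on one core.

## Known limitations

* The medial end of the PPfpm is deliberately not extracted; the printed
  evidence shows it cannot be identified reliably, and the extent metrics
  are defined without it.
* The generator's shape classes are discrete; real profiles arguably lie on
  a continuum.
* Manual quality control of extracted landmarks (a human procedure in the
  original workflow) is represented only by exclusion flags in the
  metadata, not replicated.
* Effect sizes beyond the printed quantities (e.g. η²) are not computed.
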