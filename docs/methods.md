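# Methods

This note documents the models and procedures implemented in `precistep`,
the defaults and why they were chosen, and what the synthetic data do and
do not establish about real recordings.

## Task and protocol

A walker on a treadmill (belt speed 3 km/h = 0.8333 m/s) steps on targets
projected onto the belt. Targets are belt-fixed: each appears 2 m ahead of
the walker and approaches at belt speed. Anteroposterior (AP) spacing
equals the walker's preferred step length L; mediolateral (ML) spacing is
20 cm center-to-center; target size equals the shoe. Feet strictly
alternate with target index.

A session holds one *unperturbed* block (59 targets, no shifts) and three
*perturbed* blocks (248 targets, 40 shifts each) in seeded random order.
The 40 shifts comprise 8 repetitions of each of five types — forward jumps
of 0.4 L triggered at ARDs of 0.8, 1.0, 1.3 and 2.0 L, plus backward jumps
of 0.4 L at ARD 1.3 L (included only to prevent anticipation; excluded from
summaries) — with 4 per foot per type and 5–7 non-shifted targets between
consecutive shifts.

**Gap schedule.** 40 gaps of 5–7 fillers would need 200–280 non-shifted
targets, but a 248-target block has exactly 208. Gaps (including the
lead-in before the first shift) are therefore drawn uniformly from
{5, 6, 7} and randomly decremented towards 5 until they fit, leaving any
remainder as a tail after the last shift. Because feet alternate with
index, the "4 per foot per type" balance additionally requires the 40
shift indices to split 20/20 between even and odd; draws violating this
are rejected and resampled (acceptance probability is high; the sampler is
effectively instant). This is one consistent reading of a design whose
lead-in/tail bookkeeping is underdetermined; the printed totals (248
targets, 40 shifts, gaps 5–7) hold exactly.

**Shift trigger.** A shift is realized at the first COP sample at which
the target's lab-frame AP distance from the COP is at most ARD × L.

**Coordinates and units.** AP positive in the walking direction; ML
positive to the walker's left; the lab frame origin sits at the walker's
mean COP; the belt frame is fixed to the moving surface. Meters and
seconds internally; % of L only at reporting boundaries.

## Synthetic walker

The simulator produces the two signals the analysis consumes — 150 Hz
3-D trajectories of six shoe markers (toe = 3rd metatarsal head, lateral
malleolus, heel per foot) and a 1000 Hz COP trajectory — plus ground truth
for every downstream stage.

*Landing model.* The step onto target *i* lands with a signed AP error
drawn from `N(error_bias · L, (sigma · kappa(ard) · L)²)` about the
(displaced, if shifted) target center. `kappa(ard) ≥ 1` is non-increasing
in ARD: shorter response distances produce sloppier landings. Defaults:
kappa = 1.6 / 1.4 / 1.2 / 1.0 at ARD 0.8 / 1.0 / 1.3 / 2.0 (linearly
interpolated in between). These inflation factors are calibration choices
of this package, not measured values; the ARD effect direction follows the
qualitative expectation only.

*Cohort model.* Ages uniform on 9–18.5 years. Landing variability follows
`sigma(age) = sigma0 + b · age` plus between-subject noise
(`sigma0 = 0.090`, `b = −0.003 /yr`, between-subject SD 0.011, floored at
0.005; all fractions of L). With ages uniform on 9–18.5 this yields a
population age–variability correlation of ≈ −0.6 at the sigma level — a
moderate, age-declining variability typical of developmental cohorts. The
mean landing bias is age-invariant (1 % L ± 1 % L between subjects), so
mean error carries no age signal. Preferred step length grows weakly with
age (0.35 + 0.012·age m ± 0.03).

*Kinematics.* Strikes are strictly periodic at the target-arrival period
T = L/v; stance lasts 1.2 T (double-support fraction 0.2); stance feet
ride the belt at −v; swing follows a minimum-jerk AP profile with a
half-sine vertical lift (apex 5 cm). Marker offsets are rigid per foot
and their AP components sum to zero, so the marker centroid is exactly
the foot center. The COP progresses linearly heel-to-toe under the
single-support foot (−0.40 to +0.45 shoe lengths) and transfers in a
straight line during double support, reproducing the butterfly pattern.
Sensor noise is additive white Gaussian (defaults: 1 mm markers, 2 mm
COP). Every stochastic call takes an explicit seed or generator.

*Known geometric artifact.* At the shortest ARD (0.8 L) the COP-distance
trigger can realize within ~50 ms around the landing instant (the
late-stance COP sits ≈ 0.85 L behind the approaching target in this
geometry). Scoring is unaffected — the onset always precedes midstance,
which is what selects the displaced center — but shift-onset timing at
ARD 0.8 should not be interpreted as a faithful reaction-time stimulus.

*Error-level path.* `simulate_step_errors` draws landing errors from the
identical model without synthesizing signals. It exists for
statistics-scale studies (hundreds of cohorts); the signal path is
validated separately (tests show score ≈ truth to < 0.5 mm noiseless) and
a pipeline test checks both paths agree statistically.

## Event detection

The ML COP alternates between two single-support plateaus joined by fast
double-support ramps. Plateaus are segmented by hysteresis thresholding at
±25 % of the robust ML amplitude around the midline; each ramp's central
portion (25–75 % of the level span) is fitted with a least-squares line and
intersected with the neighbouring plateau medians. The intersection with
the outgoing plateau is the incoming foot's strike; with the incoming
plateau, the outgoing foot's toe-off. On noise-free synthetic input events
are exact to numerical precision; with 2 mm ML noise they stay within a
few ms (the tests assert 10 ms noiseless / 20 ms noisy, conservative
bounds). The detector refuses input without at least four plateaus
(two strides) or without a usable ML amplitude, with a diagnostic.

Midstance of a stance is the midpoint between the contralateral toe-off
and its subsequent heel strike. Leading/trailing stances without a
complete contralateral bracket are skipped; inconsistent interior pairings
raise an error naming the orphan event. Preferred step length is the mean
AP distance between successive foot-strike COP positions plus the belt
displacement `v·Δt`, over 20 strides by default.

## Scoring

Foot center = centroid of the three markers (identical to the center of
the midpoints of the three connecting segments); marker dropouts are
bridged by linear interpolation within a 33 ms window, else the step is
dropped and logged. Target center at midstance is recomputed from the
protocol and belt kinematics, using the displaced center once the
recorded shift onset precedes midstance. The signed error is
`AP(foot) − AP(target)`, positive = overshoot.

Normalization order: raw errors are averaged first, then expressed as
% of L; variability uses the population (divide-by-k) SD of raw errors,
then % of L. Per-ARD summaries are computed per condition and then
averaged (unweighted) into the pooled perturbed measures. Targets whose
events cannot be matched (nominal arrival > half a step period from any
strike, or foot mismatch) are dropped and logged; on clean input nothing
is dropped.

In the full pipeline the normalizing L is measured from the unperturbed
block's detected strides, as a study would do, not taken from the
configuration.

## Cohort statistics

* `pearson_corr` — product-moment r, two-tailed t-based p (scipy).
* `partial_corr` — double residualization against an intercept plus the
  covariates; df = n − 2 − c; collinear covariates or zero residual
  variance are errors.
* `rm_ancova` — univariate mixed-model form. Between-subject covariate
  (age, centered) tested on subject means with df (1, n − 2). Within
  effects (condition, condition × age) tested on orthonormal
  within-subject contrasts with uncorrected dfs (k − 1, (k − 1)(n − 2));
  Greenhouse–Geisser epsilon is estimated from the residual contrast
  covariance after removing the covariate (ε = (tr S)² / ((k−1) tr S²),
  clipped to [1/(k−1), 1]) and multiplies both dfs, preserving
  df2/df1 = n − 2. GG rather than Huynh–Feldt is implemented because the
  fractional-df structure it produces is the one this design reports.
  Missing cells are an error — no imputation.
* `fdr_bh` — Benjamini–Hochberg step-up at level q over an explicitly
  supplied family (family composition is the caller's responsibility);
  backed by statsmodels, verified against a brute-force step-up oracle.
* `permutation_pearson` — two-sided `p = (1 + #{|r_perm| ≥ |r_obs|}) /
  (n_perm + 1)` over seeded permutations (default 5000).

Null calibration: over simulated null cohorts (n = 30, k = 4) the
GG-corrected within-subject tests reject at ≈ 0.04 and the covariate test
at ≈ 0.05 at α = 0.05 (the GG correction is mildly conservative under
sphericity, as expected).

## Problem sizes and numerical choices

The test suite and acceptance script use the full printed design for
protocol and single-trial checks (59- and 248-target blocks), 200 and 100
cohorts of 30 respectively for correlation-recovery estimates, 500 and 300
null cohorts for ANCOVA calibration, and reduced blocks (13–70 targets,
2 shifts per type) for multi-subject full-signal pipeline runs — sizes
chosen to keep runs quick while leaving Monte-Carlo error well inside the
asserted tolerances. Ties in the shift trigger resolve to the first
qualifying sample; degenerate inputs (singleton conditions, coincident
toe-off/heel-strike, zero-variance correlates) are either defined results
(variability 0, flagged midstance) or explicit errors, as documented per
function.

## What the synthetic data do not show

The simulator emulates the statistical structure the analysis assumes —
periodic gait, butterfly COP, Gaussian landing errors with an
age-declining spread, rigid marker geometry — not real biomechanics. It
contains no step-timing adjustments to shifts, no ML landing errors, no
drift, marker occlusion bursts, soft-tissue artifact, or force-plate
crosstalk. Passing tests therefore establish that the pipeline's
arithmetic is faithful and that its estimators recover known ground truth
under the assumed signal model; they do not certify event-detection
parameters (thresholds, windows) against real force-platform recordings,
which should be re-validated on instrumented data before substantive use.
Brain measures enter only as precomputed per-subject covariate tables; no
imaging computation of any kind is performed.
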