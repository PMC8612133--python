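# Methods

This note documents the models, estimators and design choices behind
`metaadvice`, in the spirit of a statistical methods appendix.

## Task and staircase

The simulated task is a two-alternative perceptual discrimination: 68
"aliens" in two colours, the participant reports the majority colour.
Sessions have 30 practice trials (feedback, no confidence rating) and
80 main trials (confidence rating, no feedback); on exactly half of
the main trials — round(0.5·80) = 40, drawn uniformly — an advisor
names a side and the participant may revise their choice.

Difficulty is the count difference Δ, driven by a 2-down-1-up
staircase: two consecutive correct responses shrink Δ by one step, any
error grows it, with clamping at the bounds and the two-correct
counter reset on every Δ change. The fixed point is the accuracy p
solving p² = 0.5, i.e. √0.5 ≈ 0.707. Defaults: Δ₀ = 20, step 2,
bounds [2, 66]; all bounds share the parity of the 68-alien display so
both colour counts stay integral. The staircase runs through practice
and main trials; accuracy summaries exclude the 30 practice trials as
burn-in. These step parameters are package defaults (the underlying
experimental literature rarely reports them); the convergence tests
only rely on the 2-down-1-up fixed point, not on the particular step
size.

## Generative observer

- **Decision.** Evidence x ~ N(±s·Δ/2, 1) (sign by majority side),
  choice by comparison with criterion c. Default sensitivity slope
  s = 0.06 d′-units per count puts the staircase equilibrium near
  Δ ≈ 18 (d′ ≈ 1.1), matching a ~70%-accuracy threshold task.
- **Confidence.** The meta level re-reads the evidence through
  additive noise ν ~ N(0, σ_m) and maps the normalised distance from
  the criterion through a logistic:
  conf = clip(2·σ(g·|x+ν−c|/√(1+σ_m²)) − 1 + bias, 0, 1), g = 1.5.
  The √(1+σ_m²) normalisation makes the observer calibrated to its own
  noise scale: raising σ_m destroys confidence-accuracy *coupling*
  without inflating *mean* confidence. (Without it, noisy observers
  are paradoxically the most confident, because noise inflates the
  expected distance |x+ν|.) σ_m = 0 recovers the ideal metacognitive
  observer, whose fitted meta-d′/d′ ≈ 1.
- **Advice.** The advisor is independently correct with probability
  0.7 on each advice trial (i.i.d., not stratified), naming the true
  majority side when correct. The schedule is drawn before the
  session, so advisor correctness is independent of the participant's
  behaviour.
- **Switching policy.** P(switch) = baseline (0.05) when advice
  agrees; baseline + trust·slope·(1−conf), clipped to [0,1], when it
  conflicts (slope 1.6). This is the minimal policy that produces all
  three target phenomena: positive propensity, confidence-mediated
  resistance to false advice, and zero discrimination when either
  trust or the confidence dependence is switched off.
- **Second confidence rating.** Generated (first rating plus small
  noise) so trial records are complete, but not analysed.

## Cohort maps

Default cohort: 8–9 y (n=30, 11 male), 12–13 y (n=41, 19 male),
16–17 y (n=36, 15 male); ages uniform in each group's observed range.
Three age/sex-dependent parameter maps encode the developmental
structure the simulator is meant to emulate (values chosen once, as
plausible magnitudes that produce the qualitative pattern at n = 107;
nothing in the estimation code depends on them):

- meta-level noise σ_m = 0.45 + 1.85·r(age) + N(0, 0.5), truncated at
  0, where r ramps from 1 at age 8 to 0 at age 12 and stays 0 — an
  adolescent-emergent *gain* in efficiency. The jitter creates the
  within-group individual differences that the mediation's b path
  needs.
- confidence bias = 0.02 + 0.12·Gaussian bump centred at 13.1 y
  (width 3 y) + 0.06·[male] + N(0, 0.04) — an early-adolescent
  confidence peak, males above females.
- advice trust = 0.6 + 0.45·r(age) + N(0, 0.1), truncated at 0 — an
  emergent *decrease* in advice-following.

With these defaults the simulated raw propensity scores are larger
than typically observed in children (the policy's conflict term is
deliberately strong so the resistance effect survives the heavy
binomial noise of ~17 conflict trials per participant); analyses use
z-scored scores, so only the ordering matters. A null cohort (all
effect-size fields zero) is available for calibration studies.

Per-participant RNG streams derive from (master seed, participant
index), so cohorts are bit-reproducible and participants keep their
streams when the cohort grows.

## Metacognition measurement

Bias is the mean first confidence over main trials. The continuous
ratings are binned into K equal-width levels (default K = 6,
right-closed at 1) — a common compromise between resolution and cell
occupancy at 80 trials; results should be checked for sensitivity to
K rather than assumed stable. Counts get Hautus-style padding
(1/(2K) per cell) before both the type-1 estimates
(d′ = z(H) − z(F), c = −(z(H)+z(F))/2) and the likelihood; padding is
configurable off.

meta-d′ maximises the multinomial log-likelihood of the
confidence-level counts conditional on (stimulus, response) under an
equal-variance Gaussian meta-level model with distributions at
±meta-d′/2 and the type-1 criterion mapped to c′ = c·(meta-d′/d′).
Free parameters: meta-d′ and 2(K−1) type-2 criteria, kept ordered by
parameterising them as cumulative exponentiated increments away from
c′. Optimisation is bounded L-BFGS-B from 5 multistarts (meta-d′
started around d′ and at perturbed values), absolute likelihood
tolerance well below 1e-6; cell probabilities are floored at 1e-12
before the log. Negative meta-d′ values — estimation error around a
non-negative quantity — are retained by default, with a
clamp-to-zero variant for robustness analyses. Participants whose
binned ratings occupy fewer than two levels, or who never use one of
the responses, are flagged non-estimable and carry missing
efficiency; with default cohort noise this affects roughly 0–5 of 107
simulated participants.

The test suite checks the fit against an independent profile-likelihood
grid search (coarse-to-fine down to 1e-4 in meta-d′, Nelder-Mead over
criteria at each grid point); agreement is ~3e-5 on random small
tables, well inside the 1e-3 test tolerance.

A note on sampling noise: the efficiency ratio of an ideal observer
estimated from 10,000 trials has a standard deviation of ~0.06 at
threshold difficulty (d′ ≈ 1.1) but ~0.03 at d′ ≈ 1.8, because type-2
information grows with signal strength; the recovery checks therefore
use the stronger-signal condition.

## Advice scores

Propensity = P(switch | disagree) − P(switch | agree); resistance =
P(follow | initially wrong & conflicting) − P(follow | initially
right & conflicting). Because a correct advisor names the majority
side, conflicting advice is helpful exactly when the first choice was
wrong; the classification is derived from the participant's own
accuracy, never from the advisor's latent flag alone. Any participant
with an empty denominator cell gets a missing (never zero) score and
is dropped pairwise from the affected analysis. Scores are z-scored
(sample SD) across included participants before regression.

## Age-trajectory comparison

Linear age = z-scored raw age; quadratic = its square;
adolescent-emergent = the quadratic transform of raw age clamped at
12 years (participants above 12 share the age-12 value; z-scoring
precedes the square and uses the unclamped sample mean/SD). The
literal definition ("replacing values above 12 with the same value")
is ambiguous about clamp-then-transform versus transform-then-replace;
clamping raw age before the quadratic evaluation is used here and the
plateau age is configurable. Note the emergent predictor *decreases*
toward its plateau, so a positive developmental gain appears as a
negative coefficient.

Seven candidates (the non-empty subsets of the three predictors), each
plus a sex covariate (female = 0, male = 1), are fitted by OLS on the
identical complete-case set and compared by
BIC = k·ln(n) − 2·lnL, with k counting intercept, predictors, sex and
the residual variance. The residual variance entering lnL is floored
at 1e-12·var(y) so numerically perfect fits tie in likelihood and the
complexity penalty decides. Group-level tests are two-sided
independent t-tests with pooled-SD Cohen's d and one-way ANOVA with
partial η²; α = 0.05, uncorrected.

## Mediation

X = adolescent-emergent age, M = metacognitive efficiency,
Y = resistance to false advice, covariate sex; X, M, Y standardised.
Point estimates by OLS: a from M ~ X + sex; b and c′ from
Y ~ X + M + sex; c from Y ~ X + sex; ab = a·b. The identity
c = c′ + ab is exact on complete cases. Inference: case-resampling
bootstrap (default 10,000 draws; covariates stay attached to rows),
BCa intervals with bias-correction z₀ = Φ⁻¹(fraction of bootstrap
draws below the point estimate) and acceleration from jackknife
skewness; the two-sided p inverts the CI over an α grid of step 1e-4
(a normal-approximation p is reported alongside). Verdict: "none"
unless a, b and ab are all significant; among those, "full" if c′ is
not significant, else "partial". The ab test's empirical type-I error
sits in the nominal calibration band in the suite's 500-replicate
null study.

## Problem sizes used in the test suite

Convergence and calibration checks use 100 sessions, 1e5-trial
staircase and advisor runs, 1e4-trial metacognition recoveries, 200
replicates per trajectory for BIC model recovery, 500 null / 200
power replicates (1,000 bootstrap draws each) for mediation
calibration, and 5 full pipeline replicates (2,000 draws) for the
end-to-end pattern — sizes at which each check's Monte-Carlo error is
small relative to its acceptance band.

## What the simulator does and does not show

Passing tests demonstrate that the estimators recover the generative
quantities under the model's own assumptions (Gaussian evidence,
logistic confidence read-out, the stated switching policy) and that
the full pipeline reproduces the qualitative developmental pattern it
encodes. Real data differ in ways the generator does not emulate:
lapses and response biases, non-stationary confidence criteria,
sequential dependencies, heterogeneous sensitivity slopes, and
advice effects beyond a single scalar trust weight. The measurement
chain is agnostic to these (it consumes trial tables), but the
qualitative-reproduction results should not be read as evidence about
human participants.

## Known limitations

- meta-d′ is fitted response-unconditionally; response-conditional
  variants are out of scope.
- The one-way ANOVA's partial η² equals η²; no factorial designs.
- The BCa p-value by CI inversion can differ slightly from toolbox
  implementations that use a bootstrap-z approximation; both are
  reported.
- The emergent predictor's plateau rule is one of several readings of
  the construct; alternatives can be had via `plateau_age` and by
  transforming before clamping externally.
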