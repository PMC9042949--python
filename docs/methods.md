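# Methods

`morphopath` implements a complete analysis chain for studies that relate
facial shape and skin colour to socially perceived traits: landmark-based
geometric morphometrics feeding a layered Bayesian path model in which age
and body mass act on a block of correlated facial measurements, and those
measurements in turn predict two correlated perceived outcomes (sex-
typicality and dominance). A calibrated synthetic-study generator provides
recoverable ground truth for every stage. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish.

## Geometric morphometrics

**Superimposition.** Configurations of 72 two-dimensional landmarks (36
fixed points, 36 semi-landmarks on four curves: jaw outline, two brows,
upper lip) are superimposed by generalized Procrustes analysis: each
configuration is centred, scaled to unit centroid size, and rotated to the
running consensus; the consensus is the arithmetic mean re-normalised to
unit centroid size, which is exactly the unit-size shape minimising the
summed squared distances, so the outer loop is a coordinate descent with a
non-increasing objective. Reflections are never admitted (faces have a
consistent orientation). Convergence: root-mean-square consensus change
below 1e-6, at most 20 outer iterations; typical samples converge in under
ten. Tangent-space projection after superimposition is available as an
option but off by default — at facial shape-variation magnitudes
(Procrustes distances ~0.05) it changes downstream scores negligibly.

**Sliding semi-landmarks.** With sliding enabled, each semi-landmark is
displaced along its local tangent (the normalised chord between its curve
neighbours; one-sided at curve endpoints) to the position minimising that
specimen's squared Procrustes distance to the consensus — a closed-form 1-D
projection of the residual onto the tangent. The displacement is capped at
half the distance to the nearer neighbour to prevent curve inversion. The
Procrustes-distance criterion is used because the tangential position along
a curve carries no shape information under that criterion; the
bending-energy alternative used by some toolkits is not implemented.
Because the tangential coordinate is a nuisance degree of freedom, the
whole sample can drift collectively along its curves if sliding alternates
with re-superimposition indefinitely; sliding therefore runs for a fixed
number of outer passes (default 5, in line with common toolkit defaults)
before the final, convergent plain superimposition.

**Shape statistics.** Three per-face statistics are computed on the pooled
two-sex superimposed sample:

* *SShD* — projection of the flattened 144-coordinate configuration onto
  the unit vector from the female to the male mean shape, centred at the
  midpoint between the two sex means. Midpoint centring makes the two sex
  means land symmetrically (±separation/2), matching the opposite-sign sex
  means reported for such scores; lower values are more female-like.
* *DIST* (distinctiveness) — Procrustes distance from the sample consensus.
* *Shape dominance / shape sex-typicality* — each centred coordinate is
  regressed on the standardised perceived rating, and the face's score is
  the projection of its centred configuration onto the *raw* coefficient
  vector. The raw (un-normalised) vector keeps scores on the ~1e-4 scale
  typical of published per-face regression scores; since every variable is
  standardised before modelling, the normalisation convention is
  immaterial downstream. These regressions run within sex (ratings exist
  per sex), while SShD requires the pooled two-sex superimposition because
  the inter-sex axis is otherwise undefined.

## Reliability, colour and anthropometrics

Interrater agreement uses the two-way consistency, average-score intraclass
correlation, ICC(3,k) = (MS_stimuli − MS_error)/MS_stimuli, with raters
treated as fixed; stimuli with any missing rating are dropped listwise.
Ratings are then averaged per stimulus.

Repeated facial width/height measurements pass a repeatability gate: the
pair is accepted and averaged only if their Pearson correlation exceeds
0.9; failure raises an error carrying the observed r.

CIELab channels may enter the model separately or be replaced by one latent
"colour" variable. The decision is rule-based: Horn's parallel analysis
(observed correlation-matrix eigenvalues against the mean eigenvalues of
independent standard-normal matrices of the same shape) must retain exactly
one factor *and* the maximum pairwise channel correlation must exceed 0.8.
The factor is fitted by iterated principal-axis factoring (just-identified
with three indicators, so the method choice barely matters); scores use the
Thurstone regression method (mean 0, variance ≤ 1) with the sign oriented
so L* loads positively; a Heywood communality is clipped at 0.995 with a
warning. One caveat worth recording: at the exact null (independent
channels), the mean-reference retention rule compares two draws from the
same eigenvalue distribution, so it retains a marginal first factor with
probability near one half regardless of sample size — the null behaviour
of parallel analysis is only meaningful statistically, and a 95th-percentile
reference is available as an option.

## The path model

All variables are standardised within each sex-by-population sample. The
directed structure is: age exogenous; BMI ~ Normal(intercept + slope·age);
the m mediators jointly multivariate normal with means linear in age and
BMI and an unstructured residual correlation matrix; the two perceived
outcomes bivariate normal with means linear in age, BMI and all mediators
and a residual correlation — deliberately non-directed between the two
outcomes. Variants: *default* (mediators = 3 colour channels or 1 colour
factor, plus fWHR, SShD, DIST), *extended* (adds both shape-trait scores),
and two partial variants adding exactly one. With six mediators this gives
9 intercepts, 29 slopes, 6+15 mediator variance/correlation parameters and
2+1 outcome parameters; the extended variant gives 11/37/8+28/2+1. The BMI
residual sd is also sampled (Exponential(1)) but kept in its own manifest
category so the counted categories match the published accounting.

Priors: Normal(0, 0.2) intercepts, Normal(0, 0.5) slopes, Exponential(1)
sds, LKJ(η = 2) on both residual correlation matrices (used unnormalised;
constants cancel in sampling). Likelihood evaluation uses per-block
cross-product matrices, so its cost is independent of n.

**Sampling.** The posterior is explored by blocked Gibbs with Metropolis
steps, written against the module's own `log_density`:

* the three regression-weight blocks (BMI, mediators, outcomes) have exact
  multivariate-normal full conditionals given the residual covariances —
  posterior precision Σ⁻¹⊗XᵀX plus the diagonal prior precision — and are
  drawn exactly each iteration;
* sds (log scale, with Jacobian) and correlation entries are updated by
  componentwise random-walk Metropolis; proposals breaking positive
  definiteness are rejected; proposal scales adapt toward 44% acceptance
  during warm-up only, preserving detailed balance afterwards.

Defaults: 10 000 retained draws over 4 chains, warm-up half of each chain.
Diagnostics are split-R̂ and bulk ESS (via arviz); the `converged` flag
requires R̂ ≤ 1.01 and ESS ≥ 400 everywhere. Correctness is established by
three routes: a zero-data fit reproduces every prior margin (KS < 0.05 at
10 000 draws, including the Beta((d−2)/2+η, ·) pairwise-correlation margins
implied by LKJ); fixing a residual sd reduces one block to an exact
conjugate normal posterior that the sampler matches within Monte-Carlo
error; and a 50-replicate simulation at n = 150/sex gives pooled 95%-interval
coverage of the generative slopes in the nominal band with per-slope bias
below 0.05. Summaries are posterior means with central 2.5%/97.5% quantile
intervals; the outcome residual dependence is reported as the correlation
parameter itself (variables are standardised). Rows with missing variables
are dropped with a logged count; measurement error in ratings is not
modelled.

## Synthetic-study generator

The generator is the generative mirror of the fitted model, so every
downstream estimate has a recoverable truth. Standard-normal age drives
BMI; age and BMI drive the mediator block with a chosen residual
correlation matrix; mediators drive the bivariate latent outcomes with a
chosen residual correlation. Residual sds default to the values making
every variable unit-variance, so within-sample standardisation leaves
generative slopes interpretable; explicit residual sds (including zero, for
degeneracy tests) can be supplied.

Shape: the packaged template is a schematic frontal face with unit centroid
size; the dimorphism axis is a masculinising deformation (wider jaw and
zygia, lower brows, thinner upper lip, longer chin), centred and normalised
to a unit 144-vector. A specimen's configuration is the template plus
(sex offset ± separation/2 + within-sex latent)·axis, isotropic
idiosyncratic noise (its per-specimen scale modulated by the DIST latent),
tangential semi-landmark jitter, and a nuisance similarity transform
(rotation uniform on [0, 2π), scale log-uniform on [0.5, 2], translation)
so superimposition is genuinely exercised. The separation and noise scales
are set from the published per-sample descriptive moments: separations of
0.04 (European) and 0.02 (Cameroonian) in Procrustes units with within-sex
latent sds of ~0.01 reproduce per-sex SShD score means of roughly ±0.01 to
±0.02 and SDs in the 0.01–0.02 band, and idiosyncratic sds of 0.004–0.005
per coordinate put mean distinctiveness at 0.05–0.06.

Ratings: latent outcomes are affinely rescaled to each preset's published
mean/SD of per-stimulus mean ratings, then perturbed per rater (sd 1.2,
residual-only; rater main effects are available but off by default, since
no rater-level variance decomposition is published), rounded and clamped to
the 1–7 integer scale. Rounding and clamping are the simplest response
model producing integer Likert data. The rater count is 102 per scale, the
published mean raters-per-set; at that count the induced ICC(3,k) exceeds
0.95. Facial width/height measurement pairs are generated from the latent
fWHR with additive measurement noise calibrated to pass the 0.9
repeatability gate.

Four presets reproduce the four published samples (Czech/Cameroonian ×
women/men): covariate and colour moments, rating moments and sample sizes
follow the published descriptive table; generative path slopes and residual
correlations are set to the corresponding published posterior means
(unreported slopes zero). Czech presets use moderately correlated channels;
Cameroonian presets generate the channels from one latent factor with
loadings matching the published per-channel variance explained. Everything
is deterministic given the seed, file output included.

**What the generator does not emulate.** Faces are schematic, not
photorealistic; digitising error is isotropic Gaussian rather than
landmark-specific; the width/height columns derive from the latent ratio,
not from the landmark geometry; rating scale use is symmetric (no rater
anchoring styles beyond iid noise); covariates are drawn from one
calibration shared by both simulated sexes. Passing recovery tests
therefore demonstrates the correctness of the estimators under the model's
own assumptions — not robustness to the measurement idiosyncrasies of real
photograph-based data. Recovered quantities are also mildly attenuated
relative to the injected truths (measured SShD correlates ~0.95 with its
latent; mean ratings carry residual rater noise; high rating means interact
with the 7-point ceiling), which is the expected behaviour of the real
measurement chain, not an estimator defect.

## Diagnostics and reporting

VIF for each predictor is 1/(1−R²) from an ordinary least-squares
regression of that predictor on the rest (with intercept), computed on the
standardised predictor set of the model variant under scrutiny; perfect
collinearity reports as infinite with a warning. Figures are marginal
posterior density panels (mean and 95% bar; constant margins render as a
spike) and forest plots of slopes and correlations. The pipeline writes a
run report with input hashes, per-stage logs, ICC values, the colour-mode
decision and VIFs; deterministic stages are bit-stable across reruns under
a fixed seed, and sampled summaries are exactly reproducible because the
seed fixes the chains.

## Problem sizes used in the shipped checks

Structure identities are data-free. Prior recovery uses 10 000 draws.
Slope-coverage simulations use 50 replicates of n = 150/sex with 1 500
retained draws per fit — posterior means and 95% bounds are already stable
at that depth, and slope margins mix fast because they are drawn from exact
conditionals. End-to-end preset recoveries run at the published sample
sizes (49–106 per focal sex) and average a handful of replicate studies
because a single correlation estimate at n ≈ 50 carries sampling error of
~0.13 — the replicate mean is the expected recovered value under the study
conditions.
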