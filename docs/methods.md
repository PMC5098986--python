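# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the `coucal` package.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study system and scope

Two coucal species breeding sympatrically in the Usangu wetland (Tanzania)
differ radically in sex roles: black coucals are classically polyandrous
with male-only incubation and provisioning; white-browed coucals are
socially monogamous with biparental care.  The package quantifies that
contrast along four axes — incubation interruption patterns from
nest-temperature loggers, provisioning and "off-time" behaviour from timed
nest watches, nestling growth curves, and prey composition — and, because
the underlying field data are not public, ships a synthetic-data generator
that reproduces the statistical structure of each input stream with known
truth.  Passing tests therefore demonstrate correctness of the estimators
under the generating models, not properties of the real populations.

## Absence-bout detection

Loggers report nest temperature every 3 min in 0.5 °C steps.  An absence
bout starts with a *steady drop* of at least `drop_threshold` (2 °C) and
ends at the first sample at least `drop_threshold` above the running
minimum recorded during the bout.  Numerical choices:

- *Steady drop* is a decline run: samples that fall or stay level, with an
  isolated uptick of at most `jitter_tol` (default 0.5 °C, the quantization
  step) tolerated; two consecutive upticks end the run.  Strict
  monotonicity is unusable on quantized data (slow cooling produces
  plateaus), and without an uptick allowance measurement jitter splits
  single bouts.
- The bout start is the first falling sample of the run; the cumulative
  fall is measured from the sample immediately before it.
- The detector uses only temperature differences, so its output is
  invariant under adding a constant to the trace (tested).
- A new drop before a prior bout's recovery is the same, ongoing bout.
- Bouts still open at the end of a trace are emitted flagged and excluded
  from duration summaries; bouts containing a cadence gap > 2× the nominal
  interval are flagged unreliable.
- Only the diurnal window 06:00–19:30 (the outer bounds of the
  morning/noon/afternoon bins [06:00, 10:30), [10:30, 15:00),
  [15:00, 19:30)) is analysed; a bout is kept if any part of it overlaps
  the window, and is assigned to the bin of its midpoint.  Night-time
  attendance is not analysed — diurnal summaries are the object of study,
  and the generator keeps parents on the nest at night.

A brute-force oracle in the test suite replays the rule literally over
every candidate anchor; the single-pass detector must agree exactly on
randomized quantized traces (100 traces in the acceptance check).

## Synthetic data

- **Temperature**: first-order exponential relaxation of the logger reading
  toward a diel-sinusoid ambient while the bird is off (τ_cool = 8 min) and
  toward a 34 °C incubation level while on (τ_warm = 5 min), Gaussian noise
  (0.25 °C), then quantization.  Off-bouts per day are Poisson (black 6/day
  of ~14 min; white-browed 2/day of ~24 min — matching the observed pattern
  of more, shorter interruptions in black coucals), drawn inside the
  diurnal window, snapped to the sampling grid, overlapping draws merged.
  The ambient sinusoid (25 ± 4 °C peaking at 14:00) is a modelling choice
  consistent with the site's 20–30 °C range; no published diel profile
  exists.  With τ → 0 and zero noise the trace is an exactly computable
  square wave used for grid-exact oracle tests.
- **Focal watches**: visit counts are Poisson with mean
  `duration × exp(stratum log-rate + 0.31·z(brood mass) − 0.01·z(time) +
  parent + nest effects)`, parent and nest intercepts lognormal with SD 0.3.
  Baseline rates: black male 3.8 visits/h; each white-browed parent
  0.95 visits/h (the pair sums to about half a black male, as observed);
  black females have rate −∞ (structurally zero counts, mirroring their
  non-provisioning).  Brood mass is generated from nestling number and age
  through the logistic curve so the brood-mass and nestling-number+age
  covariate sets describe the same data.  Off-time is a clamped Gaussian
  proportion of the watch (black male 0.10, white-browed 0.25, slope
  −0.021 per SD of time of day).  Each parent gets two 60-min watches plus
  up to five more of 30–225 min.
- **Growth**: the logistic curve with bivariate-normal (A, I) shifts at
  nest and nestling level; defaults are the published per-group estimates
  (e.g. black female A = 77.1 g, K = 0.377/d, I = 6.2 d; SDs of 5.6–14.5 g
  and 0.4–1.0 d with correlations −0.2…0.8).  Residual SD defaults to 4 g
  (not published; chosen as a realistic measurement + biological residual
  for nestlings weighed to the nearest gram).  Design: 60 nests × 2
  nestlings, measured at ages 1, 3, …, 15 d.  Negative simulated masses are
  truncated at 0.1 g and flagged rather than resampled, keeping draws
  reproducible.
- **Incubation checks / prey**: Bernoulli draws of the incubating sex on a
  logit scale with nest intercepts; multinomial prey tallies.

Features of real data deliberately *not* emulated: nest predation and
failure, season/year structure, logger placement artefacts, observer
effects, non-Poisson overdispersion beyond the lognormal intercepts.

## Mixed-model estimation

Binomial-logit and Poisson-log GLMMs with random intercepts for one or two
(crossed) grouping factors are fitted by Laplace-approximate maximum
likelihood: for candidate variance parameters, a damped Newton iteration
finds the joint penalized mode of (β, b); the Laplace marginal likelihood
(mode value minus half the log-determinant of the scaled precision) is
maximized over log-SDs by Nelder–Mead, with the mode warm-started between
evaluations.  Wald covariance of β is the fixed-effect block of the
inverse joint Hessian, conditional on the variance estimates — the
convention of standard mixed-model software.  Accuracy of the Laplace
approximation is verified against adaptive 21-node Gauss–Hermite
quadrature (agreement to 1e-4 log-likelihood units on well-informed
single-factor problems, with the error decreasing in within-group
information as theory predicts); with variances pinned at zero the fit
reproduces ordinary GLM estimates to 1e-6.

Gaussian mixed models use a dense marginal likelihood with Woodbury
algebra on the random-effect dimension; β and the residual variance are
profiled, REML by default, optional case weights.  The off-time model is a
weighted Gaussian mixed model of the *proportion* `perch_min/duration_min`
with weights ∝ duration: a Gaussian "offset" on the identity scale is
statistically ill-defined, and the proportion formulation preserves the
quantity of interest (mean share of the watch spent perched).  Estimates
are cross-checked against `statsmodels` MixedLM in the suite.

Credible intervals: draws from N(β̂, Σ̂) — the asymptotic flat-prior
posterior — with empirical 2.5/97.5 percentiles; deterministic given a
seed.  R² follows the variance-partition scheme for mixed models:
marginal = fixed-effect variance over total, conditional adds random-
effect variance; the residual term is σ²ₑ (Gaussian), π²/3
(binomial-logit), or ln(1 + 1/λ̄) (Poisson-log, lognormal approximation
with λ̄ = exp(mean linear predictor + half the random variance)).  The
exposure offset counts as part of the fixed predictor.

Strata with all-zero counts (female black coucals) are reported
descriptively and dropped before fitting — a rate of zero has no finite
log-link estimate, and their non-provisioning is a biological fact, not a
parameter.  Complete separation in the binomial model triggers a small
ridge penalty, flagged on the fit.

## Growth-curve estimation

Per species-sex subset: fixed (A, K, I); random (A, I) only, at nest and
nestling-within-nest level, each bivariate normal — no random K, matching
the reported variance structure, and keeping the model identifiable at two
nestlings per nest.  Estimation alternates (1) penalized Gauss–Newton for
(β, b) given variance parameters with (2) Nelder–Mead maximization of the
linearized marginal likelihood over a 7-parameter unconstrained
parameterization (log SDs, atanh correlations, log residual SD), the
marginal covariance assembled nest-block by nest-block and batched across
same-shape nests.  The first variance search is multi-started from three
spread-out configurations because a single start can strand in a boundary
basin (correlation pinned at ±1); the best-likelihood candidate wins.
Convergence: relative marginal-log-likelihood change ≤ 1e-8 between
alternations (≤ 12), Gauss–Newton and Newton inner tolerances 1e-10.
Starting values: A₀ = 95th percentile of the response, K₀ = 0.37, I₀ = 6,
overridable; start-robustness is tested.  Data beyond an age cap (16 d)
are excluded — post-fledging mass loss is not modelled.  Fixed-effect CIs
come from the GLS covariance at the final linearization; variance-
component CIs from the numeric Hessian over the unconstrained scale with
delta-method back-transformation, and the positive-definiteness of that
Hessian is checked on every fit.  Exactly-fitting (zero-residual) data are
short-circuited to the nonlinear-least-squares solution, where the
marginal likelihood degenerates.

**Known limitation.**  First-order linearization — the estimator class
used here and in the reference R implementation (`nlme`), which this
fitter matches to four decimals on shared simulated datasets — carries a
small upward bias in K (≈ +1.5% at the white-browed female generating
values, where the inflection-point SDs are largest) and a smaller one in
I.  Both parameters are estimated so precisely at the 60-nest design that
these biases push their nominal-95% CI coverage to ≈ 0.8 (K) and to the
lower band edge (I), while A coverage stays nominal.  This is a property
of the method, inherited by any analysis built on it.

## Prey composition and ROPE

Each category is binomial against the rest with a conjugate Beta posterior
— uniform Beta(1,1) prior by default ("uninformed"), Jeffreys by flag; a
joint Dirichlet treatment is available but the per-category binomial is
primary, matching the behaviour of the classic Bayesian proportion test.
Intervals are central 2.5/97.5 quantiles, computed analytically.  ROPE is
P(|p_black − p_wb| < ε) under independent posteriors, Monte-Carlo with
10⁵ draws, checked against a 400-node Gauss–Legendre quadrature of the
same integral.  ε has no canonical value; it defaults to 0.05 and is a
mandatory, logged configuration entry.

## Problem sizes and determinism

Simulation studies run at the field design: growth recovery uses 100
replicates of 60 nests × 2 nestlings; Poisson-GLMM coverage uses 200
replicates of the 76 + 54-nest watch design (~550 watches each); the
detector oracle comparison uses 100 random traces of ≤ 500 samples.  Every
stochastic component flows from explicit integer seeds (SeedSequence-
spawned within studies), and the pipeline report is a pure function of
(inputs, config, seeds); rerun determinism is asserted byte-for-byte in
the tests.

## Other design choices

- Parent and nest random effects are treated as crossed in the penalized
  working model; in these data each parent attends one nest, so nesting is
  a degenerate special case that needs no special handling.
- Covariates are standardized with the analysis sample's mean/SD, stored
  on the fit for back-transformation to natural units.
- Year and date covariates are omitted (no influence in the source
  analyses); the simulator does not generate them.
- Published F-statistics and t-degrees-of-freedom conventions are not
  replicated; inference is by credible/confidence intervals throughout.
- The printed credible intervals for prey proportions were produced by an
  MCMC highest-density routine; the analytic central intervals used here
  can differ by one unit in the second decimal on a skewed posterior.
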