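# Methods

This note documents the statistical machinery, the synthetic-data
generator, the numerical choices, and the design decisions taken where
the analysis recipe left genuine freedom.

## 1. Trial screening

Reaction-time trials are screened in a fixed attribution order:
missing responses, then incorrect responses, then out-of-bounds
latencies. Bounds are a 150 ms anticipation floor (applied identically
to both tasks) and a person-specific ceiling at the intraindividual
mean + 3 SD, computed per person × task × year × session over
non-missing correct trials. Two choices matter:

- **Single pass.** Cell statistics are computed once, before any
  bound-based removal, and never recomputed. Iterating to convergence
  would remove progressively more trials than the conservative
  convention intends; with cached statistics, screening is idempotent.
- **Inclusive ceiling.** A trial exceeding its cell mean *by three or
  more* SD is removed, so equality is excluded.
- The one-back task's first trial is structurally unanalyzable (there
  is no previous stimulus to respond to) and is removed before any
  accounting, so the possible-trial denominator is 60 per session for
  both tasks.

Cells with fewer than two usable trials have an undefined SD; their
trials are retained with a warning rather than silently dropped.
Whether the ceiling should pool sessions within a year is ambiguous in
the underlying convention; the per-session default is exposed in
`QCRules.scope`.

## 2. Residualized ISD and the T metric

Within each person × task × year × session cell, latencies are demeaned
(absorbing person- and occasion-level speed differences, and with them
age-related mean speed) and residualized on the pooled within-cell trial
index, removing trial-level practice trends. The residualization is a
deterministic fixed-effects least-squares fit rather than a random-
effects model: it removes the same named confounds, is testable against
a normal-equations oracle, and has no convergence failure modes.
Regressors that are constant within cells (session, year, baseline age)
are already absorbed by the cell means and are dropped as collinear with
a warning. The ISD is the n−1 sample SD of the cell's residuals; cells
with fewer than two residuals propagate as missing occasions.

**T-standardization is baseline-referenced.** One affine map per task is
estimated on the pooled Year-1/Session-1 ISD distribution
(t = 50 + 10·(isd − m_ref)/s_ref) and applied to every occasion. The
alternative — re-standardizing within each occasion — would force every
occasion's mean to 50 and annihilate exactly the weekly and yearly
slopes the model is built to estimate; it is still available as
`TStandardizer(per_occasion=True)` for sensitivity checks. A
consequence worth knowing: the measured T metric is an affine rescaling
of the latent generating scale (the slope of the map depends on the
baseline between-person ISD spread, which includes ISD sampling noise),
so trial-level end-to-end simulations recover the *signs* and relative
structure of generating fixed effects, not their raw magnitudes.
Occasion-level recovery studies therefore simulate the model outcome
directly.

## 3. The three-level model

Sessions (level 1) nest in annual waves (level 2) nest in persons
(level 3). Codings: week is 0-based at the first session of each year
(within-burst coding, the burst-design convention; a cumulative-week
coding would conflate within- and between-wave time), year is 0-based at
baseline, age is centered at 74 years, sex is 0 = male / 1 = female.
The default fixed effects are intercept, week, year, age, sex; age×year
and sex×year interactions are available but off by default. Random
effects: person-level intercept, year slope and week slope with an
unstructured 3×3 covariance (the week slope deliberately gets its own
effect, υ10k); person-year intercept and week slope with diagonal
covariance; i.i.d. residual.

Estimation is full maximum likelihood (not REML) over each person's
available cells — missing occasions are simply absent (MAR). The fixed
effects are profiled out by GLS at each variance-parameter value;
numerically this is done by Cholesky-whitening each person block and
solving one stacked least-squares problem, which stays exact even when
the marginal covariance is nearly singular (this is what makes noise-free
identification tests recover the generating coefficients to machine
precision). Persons are grouped by identical (year, week) observation
patterns so each pattern's covariance is factorized once per likelihood
evaluation.

Variance parameters are optimized by L-BFGS-B on a log-Cholesky scale
(level-3 covariance) and log scale (level-2 and residual variances), so
every iterate is a valid covariance; bounds of ±16 on the log scale
prevent overflow. When the quasi-Newton line search stalls on the
numerical gradient, a Nelder-Mead polish runs from the incumbent and
convergence is declared only if the optimum barely moves. On failure the
level-3 structure falls back unstructured → diagonal → intercept-only,
recorded in the fit result. Fixed-effect standard errors come from
(Σ Xᵀ V̂⁻¹ X)⁻¹ — the observed-information block for the fixed effects
at the ML variance estimates — with Wald CIs and normal p-values.

Unconditional (random-intercepts-only) fits decompose total RTI variance
into between-person, within-person-across-years and
within-person-across-weeks shares.

Empirical-Bayes random effects are the exact Gaussian conditional means
G Zᵀ V⁻¹ (y − Xγ̂), validated in the tests against a dense joint-
covariance oracle assembled elementwise from the model definition.

## 4. Person-specific slopes

short_term = γ̂100 + υ̂10k and long_term = γ̂010 + υ̂01k. Age/sex
contributions are *excluded* by construction: the slopes are later used
as regressors alongside age and sex, and folding covariate effects into
them would double-count. (The δ̂-scale person coefficients are exported
in the person-year random-effects table for anyone who wants them.) A
configurable scale factor on the weekly slope supports rescaling tiny
per-week changes into interpretable odds-ratio units; it is a pure
affine contract (the default is 1, since no canonical value exists on a
T-scored outcome).

## 5. Cognitive status and outcome models

Five domain scores per assessment year are z-scored against a norm cell
keyed by age band (65–74 / 75+, using age at the classification year,
since persons cross band boundaries between baseline and follow-up) and
baseline education band (0–12 / 13+). A deficit is z ≤ −1.5
(boundary inclusive; the convention does not state strictness, and the
choice is exposed in `StatusRules`). 0 deficits → HC, 1 → CIND-S,
≥2 → CIND-M; person-years missing any domain are unclassifiable and are
reported, not silently dropped.

Status at each follow-up year is regressed on one slope predictor plus
age and sex (one predictor per model, avoiding collinearity between the
strongly correlated short- and long-term slopes), HC as referent, by
Newton-Raphson multinomial ML. Predictors are centered internally for
Newton stability and the intercept unshifted afterwards; divergence of
scale-standardized slopes beyond |β|·sd(x) > 30 is reported as
separation. Wald CIs are constructed on the log-odds scale
(OR = exp β). If an outcome category is empty the model reduces to a
binary logit with a warning. A baseline-MMSE comparison model swaps the
slope for baseline MMSE and reports a likelihood-ratio test against the
covariates-only model. Attrited or unclassifiable persons are dropped
listwise per outcome year. No multiple-testing correction is applied
across the model battery.

## 6. The synthetic-data generator

The generator emulates the reference study's structure: 304 persons
aged 64–92 (mean 74.02, SD 5.95), 208 female / 96 male, education mean
15.15 (SD 3.14); 5 biweekly sessions at baseline and 4 in each of three
subsequent annual waves (17 max assessments); 60 analyzed trials per
task per session (61 administered for the one-back task); attrition of
11.0% / 3.5% / 4.5% between waves 1–2 / 2–3 / 3–4 and 26% before the
Year-8 follow-up, monotone and independent of latent values (MAR, so
FIML remains valid); HC : CIND-S : CIND-M mix of 136 : 88 : 80; per-task
missing / incorrect / outlier injection rates defaulting to the
reference exclusion magnitudes (0.13% / 1.43% / 1.78% for the choice
task, 0.20% / 10.46% / 2.42% for the one-back task).

Latent occasion-level RTI follows the three-level model exactly, with
fixed effects defaulting to the reference estimates (e.g., weekly −0.02
and yearly +0.15 T for the choice task; −0.06 and −0.09 for the
one-back task) plus group-dependent dispersion shifts (CIND groups
higher and steeper, reflecting the established dispersion/status
association). Random-effect defaults put moderate positive coupling
between the weekly and yearly random slopes (0.39 choice-like, 0.87
one-back-like). Trial latencies are drawn around a person-specific mean
speed with SD linked linearly to latent RTI (sd_ms = a + b·latent,
defaults a = 30 ms, b = 4 ms per T unit, floored at 5 ms); the link is
linear because only its invertibility and testability matter — the
generative direction is not observable. The trial distribution is
lognormal by default (latencies are right-skewed), moment-matched so
the ms-scale mean and SD are exact; a normal option exists because the
true trial-level law is unknown. Injected outliers are implausibly slow
(5–10 SD above the cell mean) or anticipatory (40–140 ms) responses.

Domain scores put HC persons at their norm-cell mean, with one
(CIND-S) or two (CIND-M) persistent deficit domains shifted −2 norm-SDs
and 0.5 norm-SDs of noise on all scores — enough overlap for realistic
classification lability while keeping ground truth recoverable. The
norm table itself is a deterministic synthetic stand-in (the real
normative sample is not public): mean 50 / SD 10 per domain with −4 for
the older band and +3 for higher education.

What the generator does **not** emulate: apparatus timing error,
circadian/session-time effects, item content, ex-Gaussian latency
shape, non-MAR attrition, and any nonlinear time trends. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to these real-data features.

## 7. Calibration studies and problem sizes

The recovery studies in `burstrti.recovery` (also run by
`scripts/acceptance.py`) use the full reference design — 304 persons ×
17 occasions — with 40 replicates per study (20 in the faster test
variants), chosen so Monte-Carlo standard errors are a few times
smaller than the quantities recovered. The Wald-coverage study uses 100
replicates so the 90–99% acceptance band is meaningful. The multinomial
recovery study uses n = 5,000 persons per replicate and summarizes
odds-ratio estimates as exp(mean log-OR), the scale on which the
estimator is asymptotically normal.

## 8. Known limitations

- Only linear weekly and yearly trends are modeled; no quadratic or
  spline time, no autocorrelated level-1 residuals, no REML.
- The multinomial models use Wald inference; profile-likelihood CIs are
  not implemented.
- The T metric's dependence on the baseline reference distribution
  makes absolute fixed-effect magnitudes design-relative (section 2).
- CIND subtyping (amnestic vs non-amnestic), clinical adjudication and
  MMSE-based classification are out of scope.
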