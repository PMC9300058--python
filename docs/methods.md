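# Methods

## Growth model

Cross-sectional gosling biometrics (body mass in g, head and tarsus
length in mm; each bird measured once at a known age) are modelled with
the Gompertz curve reparameterised to have fixed endpoints,

    size(t) = A · exp( ln(I/A) · exp(−k t) ),

so that size(0) = I and size(∞) = A.  `A` is the sex-specific adult
asymptote and `I` the (unsexable, hence shared) hatchling size; both are
fixed a priori, which keeps `k` biologically comparable across
populations and with published growth coefficients.  `k` is the only
estimated curve parameter, in 1/day on the age axis or 1/daylight-hour
on the accumulated-daylight axis.  Goslings measured at age 0 inform `I`
only and are excluded from `k` estimation.

Sibling goslings share parents and a rearing territory, and cohorts
(colony-years) share weather and phenology, so `k` receives Gaussian,
mean-zero random effects: `k + k_i + k_ij` with cohort effect `k_i` and
nest effect `k_ij` nested within cohort.  A cohort is a *colony-year*:
the same calendar year in two colonies is two distinct rearing
environments and gets two distinct effects.

### Estimation

The model is fit by maximum likelihood (not REML), with the random
effects integrated out by a Laplace approximation:

* inner problem — for fixed `(k, σ_cohort, σ_nest, σ_resid)` the joint
  penalised least-squares mode over all random effects is found by
  damped Newton with analytic first and second derivatives.  Nesting
  makes the joint Hessian block-diagonal by cohort, so each Newton step
  factorises small per-cohort blocks (a cohort effect plus its nests);
  indefinite blocks away from the optimum fall back to a Gauss–Newton
  approximation, ridged if rounding makes it numerically singular.
* outer problem — L-BFGS-B over `k` (plus population offsets, below) and
  the three log-SDs, warm-starting the inner mode between evaluations.
  Variance components live on the log scale to stay positive; a log-SD
  below −10 is reported as a boundary (effectively zero) estimate.
* the marginal log-likelihood is `−joint(b̂) + q/2·log 2π − ½ log|H(b̂)|`
  with `q` random effects; on instances small enough for exact nested
  Gauss–Hermite quadrature the approximation is accurate to well under
  0.1 log-units (verified in the test suite).

Standard errors come from the numerical Hessian of the marginal
log-likelihood; a singular information matrix yields missing SEs with a
warning rather than an exception.  AIC is `−2·loglik + 2·p` with `p`
counting fixed effects plus the three variance parameters.

Between-population differences use one joint model with treatment-coded
offsets on `k` (Arctic colony as reference).  Wald t statistics use
df = n_nests − n_fixed_effects; software packages differ in their df
conventions, so p-values near a threshold should be read accordingly.

Starting values: `k₀` from a fixed-effects-only Brent/Newton
least-squares fit (itself polished to machine precision, which makes the
exact 24× scaling identity between the age and a continuous-daylight
clock hold to 1e-6), random-effect SDs at 10% of `k₀`.

## Daylight

Dawn and dusk follow the civil-twilight convention (sun centre at −6°),
on the view that a visually foraging herbivore can feed through Arctic
twilight; the threshold is an argument everywhere, with −0.833° giving
conventional sunrise/sunset.  Solar declination and the equation of time
use the NOAA fractional-year Fourier series; day length follows from the
closed-form sunset hour angle with its cosine clamped to [−1, 1], which
yields exactly 24 h in polar day and 0 h in polar night.  Accuracy is a
few minutes per day, far below the day-to-day variation that matters
over a rearing season.  Accumulated daylight between hatch and capture
counts whole days, hatch day inclusive, capture day exclusive; only
durations are used, so time zones are irrelevant.  No topographic
horizon or variable refraction is modelled.

A caveat on reported "feeding time" advantages of the Arctic colony: the
window-averaged daylight difference between the Arctic and North Sea
colonies is ~6 h under civil twilight and ~7.5 h when the temperate
colony's day is measured sunrise-to-sunset, while the Arctic–Baltic
difference is ~4 h and ~2 h depending on the same choices.  Such figures
depend strongly on the averaging window and twilight convention, neither
of which has a canonical definition; the package reports window means
under an explicit threshold and leaves the interpretation to the user.

## Synthetic colonies

The three shipped presets emulate the sampling structure of long-term
colony studies: 6 cohorts × ~20 nests (n ≈ 392) for the Barents Sea, 15
cohorts × ~18 nests (n ≈ 933) for the Baltic, 5 cohorts × ~8 nests
(n ≈ 116) for the North Sea; capture ages follow discretised triangular
distributions matching each colony's median and range (29 (5–42), 46
(28–63), 44 (10–86) days).  Sizes are Gompertz means with the nested
random effects on `k`, an additive relative-hatch-date effect, Gaussian
measurement residual, and instrument rounding (nearest 5 g below 600 g
and 10 g above, 0.1 mm calliper for tarsus, 1 mm ruler for head; halves
round away from zero).  Broods are 1 + Poisson draws, sexes 50/50, one
capture per gosling.

The generating growth coefficients are the published population
estimates.  The remaining generator parameters are the package's own
choices of plausible field values, fixed once: adult asymptotes
(2100/1900 g male/female mass, 95/91 mm head, 78/74 mm tarsus), hatch
sizes (65 g, 42 mm, 28 mm), mean hatch dates (≈10 July Arctic, ≈5 June
Baltic, ≈25 May North Sea, with within-colony spreads increasing
southwards as breeding synchrony relaxes), and random-effect/residual
SDs calibrated once so that simulated fixed-effect standard errors land
near the magnitudes reported for such colony studies (e.g. SE(k) ≈ 0.002
for Arctic body mass).  None of these secondary values is a measured
quantity, and parameter-recovery results are conditional on them.

When generating on the daylight clock, the daylight-axis coefficients
are the generating truth and random-effect SDs are rescaled by the
per-sex ratio of the daylight to the age coefficient.

What the generator does *not* emulate: survival/recapture processes and
size-dependent mortality (each simulated gosling is captured exactly
once, unconditionally), banding-drive clustering of capture dates
(capture ages are independent across goslings), egg/incubation dynamics,
weather, density dependence, and any trait correlation beyond the shared
nest/cohort effects.  Passing recovery tests therefore show the
estimators are correct under the stated model, not that the model
captures every feature of field data.

## Residual analyses

Residuals are observed minus predicted size from the fixed-effects-only
(per-sex) Gompertz fits, sexes pooled afterwards.  Relative hatch date
is the gosling's hatch day-of-year minus its colony-cohort mean (from
full-colony monitoring if supplied, otherwise from the data).  The
residuals enter a Gaussian linear mixed model — fixed effects for
population, relative hatch date, their interaction and sex; random
intercepts for cohort and nest-in-cohort — fit by ML through statsmodels
MixedLM, with marginal Wald F tests (containment df: n_nests − rank of
the fixed design).  Backward AIC selection drops the removable term
whose removal lowers AIC most, never removing a main effect while its
interaction remains, and stops when nothing improves; the full AIC trace
is returned.  A singular nest component triggers a documented refit
without it.

Per-colony hatch-date slopes are reported from colony-specific models
(`population_hatch_slopes`) rather than read off the pooled interaction
model.  The colonies' capture-age ranges differ, so nest-level growth
variation propagates into residuals with very different magnitudes per
colony; a pooled model's common variance components then overstate the
slope uncertainty for one colony and understate it for another
(simulation puts the pooled model's Baltic slope z-scores at SD ≈ 1.4,
the colony-specific model's at ≈ 1.0).  The pooled interaction model
remains the instrument for testing whether slopes *differ* among
colonies.  Across-year trends use the same residuals regressed on cohort
year with nest random intercepts; a drift of −5.6 g/year over a 15-year
span corresponds to ≈ −84 g in total.

## Haldane rates

`h = (X2/Sp − X1/Sp)/g` with `g = period / generation_time` (30 years /
7.5 years = 4 generations for the colonisation of the temperate sites).
`Sp`, the pooled between-individual SD of the growth coefficient, is an
input: published comparisons derive it from model-estimated SDs that are
not themselves published, so the package exposes the algebraic
back-solve (`solve_pooled_sd`) and, in the pipeline, computes its own
`Sp` as the pooled `sqrt(sd_cohort² + sd_nest²)` of the two fits —
which reflects the simulated, not the field, variance structure.  The
latitude regression of (externally) mass-corrected growth coefficients
is ordinary least squares with a 95% confidence band; the mass
correction itself is deliberately left to the user, as no canonical
formula exists for it.

## Problem sizes and determinism

Parameter-recovery checks use 50 seeded replicates per setting; the test
suite runs most of them at reduced colony sizes (~150 goslings) and the
acceptance script at full preset sizes, which keeps the whole suite in a
few minutes on one CPU.  All randomness flows from explicit integer
seeds (numpy Generator/SeedSequence); identical seeds give byte-identical
datasets and reports.

## Known limitations

* The Laplace approximation can bias `k` slightly downward (≲1%) in
  small colonies with few cohorts; the quadrature cross-check bounds the
  error on tiny instances but not globally.
* Wald inference with 5–6 cohorts is approximate; variance components at
  the boundary are flagged, not profiled.
* Homoscedastic Gaussian measurement error is assumed on the trait
  scale; real mass residuals likely scale with size.
* The fixed-`A`, fixed-`I` design means a mis-specified asymptote biases
  `k`; the package deliberately does not free these parameters.
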