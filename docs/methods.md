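# Methods

## Incorporation model

A metabolically active tissue sampled at `t` days after a diet switch
is modelled as one well-mixed pool with first-order kinetics,

    delta(t) = phi1 + (phi2 - phi1) * exp(-exp(phi3) * t),

with `phi1` the asymptotic delta value (permil), `phi2` the value at
the moment of the shift (day 0; days are real-valued and non-negative)
and `exp(phi3)` the fractional incorporation rate (1/day). Fitting on
the `phi3 = log k` scale keeps the rate positive without constraints
and makes the sampling distribution of the rate estimate closer to
Gaussian. The half-life is `ln 2 / exp(phi3)`; at `t = t_half` the
curve passes exactly through the midpoint of the gap, which the test
suite asserts as an identity.

The two-pool variant
`delta(t) = phi1 + (phi2 - phi1) * [p e^{-k1 t} + (1-p) e^{-k2 t}]`
is parameterized as `(phi1, phi2, p, k1, k2)` with `logit(p)` and log
rates internally and the identifiability convention `k1 >= k2`
(enforced by construction: `k2 = k1 * expit(d)`). Its half-life is the
unique root of the mixed decay reaching 1/2, found by bracketed Brent
search. With `p` in {0, 1} or `k1 = k2` the model collapses to one
pool; this nesting is asserted to 1e-12. On data generated from one
pool the two-pool fit is expected to fail or to hit the `p` boundary —
that behaviour is the overparametrization diagnostic, reported via
`converged`/`boundary`, never silently dropped.

## Per-individual fitting

Given the rate, the one-compartment model is linear in `(phi1, phi2)`,
so the sum of squares is profiled down to one dimension: a 64-point
log-spaced grid over half-lives from one-eighth of the tightest
sampling interval to 50x the experiment duration, followed by bounded
Brent refinement. This is deterministic, has no starting-value
sensitivity, and costs well under a millisecond per trajectory —
important because the acceptance simulations refit tens of thousands
of trajectories. Standard errors come from the Jacobian at the optimum
with the usual `sse / (n - 3)` variance estimate.

A trajectory statistically indistinguishable from constant (profiled
SSE improvement below 1e-7 of the constant-model SSE) has an
unidentifiable rate: the fit returns `phi1 = phi2 = mean`, flags
`rate_identifiable = False` and reports no half-life.

The two-pool fit uses Levenberg-Marquardt from five jittered starts
(the objective is multi-modal); non-convergence, a singular normal
matrix (condition number above 1e10) or a boundary solution is
reported, mirroring how such failures should be read scientifically.

Preconditions: at least 4 distinct time points for one pool, 6 for two
(free curve parameters plus a residual degree of freedom).

## Population model and estimation

The population model puts a Gaussian random effect `b_i ~ N(0, tau^2)`
on `phi3` (individuals differ most in how fast they turn a tissue
over, and the selected models in comparable experiments place the
heterogeneity there), optional additive sex/age fixed effects on
`phi3` under treatment coding, common `phi1`, `phi2`, and i.i.d.
Gaussian measurement error `sigma`.

The default estimator maximizes the exact marginal likelihood,
integrating `b_i` by adaptive Gauss-Hermite quadrature: at every
objective evaluation each individual's posterior mode of `b_i` is
located by damped Newton iterations with a Gauss-Newton curvature
(vectorized across individuals), and a 20-node Hermite rule is centred
and scaled there. Adaptivity matters: with fixed quadrature nodes the
weakly identified individuals of a slow tissue (a 70-day experiment
covers under two half-lives at 40+ days) are integrated so coarsely
that the population half-life acquires a 10-17% upward bias; with
adaptation the recovery simulations are unbiased to about 1% and the
rule is converged (20 vs 48 nodes agree to all reported digits).
Outer optimization is Nelder-Mead on
`(phi1, phi2, beta, log sigma, log tau)`; Wald covariance comes from a
central-difference Hessian. `log sigma` and `log tau` are floored at
`log 1e-6` so noiseless data stay finite.

Two alternatives are kept behind the same interface. A transparent
two-stage estimator (`method="two_stage"`: per-individual NLS, then a
Gaussian random-effects combination of the estimates with ML tau^2 and
GLS fixed effects) is simple and debuggable and also supports random
effects on `phi1`/`phi2` and the two-pool model — but it is *not* the
default because inverse-variance weighting is biased here: the SE of
an individual's `phi3` is correlated with the estimate itself (faster
individuals cover more of their plateau and are better identified), so
the weighted mean is pulled toward short half-lives, about -14% for a
43-day tissue at this design. A Laplace-approximate marginal-likelihood
maximizer (`method="laplace"`) is retained as a cross-check; the test
suite asserts it agrees with the quadrature estimator.

AIC is always `-2 loglik + 2 n_params` and is recomputable from the
stored fields. Likelihood scales differ between estimation methods
(observation-level for marginal/Laplace, estimate-level for
two-stage), so a candidate set for model selection must come from one
method; the selection rule itself — minimum AIC, and among candidates
within 2 units the simplest by (free parameters, fixed effects,
random effects) — is shared across the package, including the
discrimination module.

Confidence intervals: Wald on the fitting scale, with the half-life
interval as the monotone image of the `phi3` interval; or a parametric
bootstrap (simulate from the fitted model, resampling random effects
and residuals, refit, percentile interval) with a mandatory seed. In
the recovery simulations at the study design the Wald half-life
interval covers the generating value in 93-95% of 200 replicates.

## Equilibrium check

Control animals that never changed diet should show flat trajectories.
`check_equilibrium` fits a constant-mean model (2 parameters) and the
pooled one-compartment model (4 parameters) to the pooled observations
and applies the selection rule; the constant model wins any tie within
2 AIC units because it is simpler. Per-individual linear slopes are
reported as a second diagnostic. Residual variances are floored at
1e-12 so that zero-noise data (both models interpolating) yield the
analytic AIC difference of twice the parameter-count difference.

## Isotopic clock

`time_since_diet_shift` inverts the fitted curve:
`t = -log((delta - phi1)/(phi2 - phi1)) / exp(phi3)`. It is exact
(round-trip identity with the forward model) for observations strictly
between the initial value and the asymptote; at the asymptote the
elapsed time is infinite and the function raises instead of returning
a misleading number. Near the asymptote the inversion is
ill-conditioned in floating point — the property tests guard the
round-trip at gap fractions above 1% and trajectory gaps above 0.5
permil, which is also the regime in which a field application would be
sane (a delta within measurement error of the asymptote carries no
time information).

## Discrimination analysis

Discrimination is `Delta = delta_tissue - delta_diet` per isotope.
delta-13C values are lipid-normalized before differencing when a C:N
ratio is available: `delta' = delta - 3.32 + 0.99 * C:N`, the standard
arithmetic normalization, strictly increasing in C:N; the coefficients
are injectable, records without C:N are left uncorrected and flagged
(`lipid_corrected = False`), never imputed.

Group summaries report mean, SD (n-1 denominator, reported only for
n >= 2) and n per cell of any subset of tissue x diet x sex x age x
isotope. "Overall" rows are n-weighted means of the cells (the plain
mean over records); unweighted cell-mean averages can be had by
summarizing the cells and averaging them directly.

The group-structured model is a linear mixed model with an individual
random intercept (heterogeneity shared across one animal's tissues).
The fixed-effect ladder runs from intercept-only through all subsets
of the main effects to all mains plus all two-way interactions;
candidates are fitted by maximum likelihood and selected with the
shared delta-AIC rule, then the winner is refitted by restricted
maximum likelihood for the reported coefficients and 95% intervals
(ML for comparison, REML for estimation). Estimation delegates to
statsmodels MixedLM with optimizer fallbacks (lbfgs, then Nelder-Mead,
then Powell); a fit with a non-finite likelihood counts as failed. A
rank check rejects designs with empty two-way cells by naming the
cells. Because different tissues enter the experiment in different
phases (keratinous tissues grow on the pre-shift diet; liver and
muscle are sampled once post-shift), the CLI fits the model per tissue
group rather than across all six tissues.

One property of the delta-AIC < 2 / simplest rule worth knowing: with
nine candidates, a spurious binary factor survives selection whenever
its likelihood-ratio chi-square exceeds 4 (about 4.6% per factor), so
on effect-free data the intercept-only model is selected in roughly
75-85% of replicates, not ~100%. The null-selection test asserts the
measured operating characteristic.

Tissues with too few records for the full model get a Welch two-sample
comparison between diets (mean difference, Welch-Satterthwaite CI, t,
df); with equal variances and group sizes it coincides with the pooled
t test, which the suite asserts.

## Synthetic experiments

The generator reproduces the study design: 40 animals balanced 2x2 by
sex and age, 20 shifted to the marine diet at day 0 and sampled on
days 0, 4, 7, 11, 15, 19, 23, 28, 35, 55, 70; the rest stay on the
terrestrial diet as controls. Shifted trajectories follow the
one-compartment model with per-individual Gaussian deviations on the
parameters named in the random-effects spec, additive sex/age shifts
of `phi3`, and i.i.d. Gaussian measurement error. Defaults:

* measurement error SD **0.2 permil** — typical analytical precision
  of bulk-tissue isotope-ratio mass spectrometry;
* random-effect SD on `phi3` **0.25** — reproduces an
  among-individual half-life spread of roughly +-25%, i.e. up to about
  a month between extreme individuals for a 40-day tissue;
* generating half-lives per tissue x isotope: plasma 9 d (d13C) and
  4 d (d15N), blood cells 43 d (d13C) and 40 d (d15N) — the fitted
  study estimates; initial and asymptotic delta values are plausible
  tissue signatures on terrestrial and marine diets (gaps of 6-7
  permil), since the experimental diet table is not published. Diet
  signatures are likewise plausible defaults, configurable, and never
  asserted as measured values.

The discrimination generator draws
`cell mean + individual intercept + cell noise` with the intercept
shared across one individual's records; default cell means and SDs are
patterned on discrimination values measured in farmed arctic foxes
(e.g. nail d15N, adult males: 5.29 +- 0.82 permil), with diet-level
offsets applied to the blood tissues. A requested cell without a generating truth raises
an error naming the cell.

Everything is deterministic given a seed (numpy `default_rng` /
`SeedSequence.spawn` for nested replication); seeds are mandatory
arguments.

What the generator does *not* emulate: growth, isotopic routing,
digestive physiology, non-Gaussian measurement error, missing-visit
patterns, or drop-out (a dropout option exists but is off by default).
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical model at the study's design,
not robustness to violations of that model in real animals.

## Sampling-design simulation

`run_design_sim` evaluates candidate sampling schedules: for each
schedule and replicate it simulates the shifted arm, refits the
population model, and summarizes the asymptote, intercept and
half-life estimates by mean, bias, SD, 2.5/25/50/75/97.5 percentiles
and the non-convergence rate. Failed replicates are counted and
excluded from moments — never retried with fresh seeds, which would
bias the survivors. Schedules must contain day 0 and at least 4
strictly increasing points. `compare_sample_sizes` reports the
Monte-Carlo SE of the half-life versus the number of animals; under
independent individuals the SE follows `1/sqrt(n)`, so 40 animals
versus the literature-typical 5 buys a factor `sqrt(8) ~ 2.83`, which
the 500-replicate run reproduces within a few percent.

Problem sizes used by the test suite and acceptance script — 200
replicates per recovery scenario, 500 for the precision-law check, 20
animals per dataset — match the study scale; the boxplot-style
rendering of design reports is deliberately left to the caller, the
numeric table being the contract.

## Known limitations

* The marginal-likelihood estimator supports one scalar random effect
  (on `phi3`) with fixed effects on `phi3`; richer random-effect
  structures route through the two-stage combination, whose weighting
  bias for slow tissues is documented above.
* Wald standard errors for `phi1` degrade when an experiment covers
  well under two half-lives (the asymptote is then barely informed by
  data); the bootstrap is the safer interval there.
* The discrimination model assumes a single shared residual variance
  across cells; the generator can produce heteroscedastic cells, which
  the mixed model then absorbs imperfectly.
* The isotopic clock propagates no parameter uncertainty; it inverts a
  point estimate.
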