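# Methods

## Model

The relative-survival decomposition writes an individual's all-cause hazard
as population rate plus excess hazard, `h(t; x) = hP(age+t; year+t, z) +
hE(t; x)`.  `frailex` adds an individual frailty `lam` with unit mean and
variance `b` multiplying `hE`.  The unit-mean constraint is what makes the
model identifiable: any rescaling of `lam` can otherwise be absorbed into
the baseline.

Marginalizing the conditional survival `exp(-lam HE)` over the frailty
distribution `G` gives the marginal net survival as the Laplace transform of
`G` at `HE`, and the marginal observed hazard as
`hP - (L'_G/L_G)(HE) * hE`.  Two families keep this closed form here:

* gamma: `L(s) = (1 + b s)^(-1/b)`, weight `1/(1 + b HE)`;
* inverse Gaussian (unit mean, variance `b`):
  `L(s) = exp{(1 - sqrt(1 + 2 b s)) / b}`, weight `1/sqrt(1 + 2 b HE)`.

The inverse-Gaussian transform is validated against numerical integration of
`e^{-sr}` over the unit-mean IG density; it is fit-capable but the gamma
family is the default and the only one exercised by the replication studies.
PVF, compound-Poisson and positive-stable frailties would slot into the same
`FrailtySpec` surface but are deliberately not implemented.

The excess hazard uses the general hazard structure
`hE(t; x) = h0(t e^{w'alpha}) e^{x'beta}` with `w` a subset of `x`
(`time_index` selects the columns), cumulative hazard
`HE = H0(t e^{w'alpha}) e^{x'beta - w'alpha}`.  Event times are simulated by
exact inversion: `t` solves `lam * HE(t; x) = -log(1-u)`, which reduces to
the baseline quantile function.

### Baseline families

The default baseline is the power generalized Weibull with survival
`S0(t) = exp{1 - [1 + (t/sigma)^nu]^(1/gamma)}` (scale `sigma` in years,
shapes `nu`, `gamma`); its hazard covers increasing, decreasing, unimodal
and bathtub shapes, and `nu = gamma = 1` collapses to the exponential with
rate `1/sigma`, which the tests exploit as an analytic identity.  Other PGW
parametrizations in the literature permute or rescale the shape parameters;
any such relabelling rescales `(sigma, nu, gamma)` without changing the
model family, and the implementation is internally validated by
hazard/cumulative-hazard consistency oracles rather than by a particular
table of formulas.  Log-normal and log-logistic two-parameter baselines are
provided for model comparison.  Hazards and cumulative hazards are evaluated
in log space (`logaddexp`) because shape values like `gamma = 8` overflow
naive powers; at `t = 0` the hazard returns its analytic limit and raises
for `nu < 1`, where it diverges.

## Life tables

Background mortality is a grid of rates on 1-year x 1-year Lexis squares
(integer attained age x integer calendar year, optional strata).  Cell
addressing floors both coordinates; lookups above the covered range are
capped at the oldest age / latest year, lookups below it raise.  The
cumulative population hazard over follow-up integrates the piecewise-
constant rate while age and year advance together; the implementation walks
cell boundaries with a 1e-9 addressing nudge so the chaining identity
`H(age, t1+t2) = H(age, t1) + H(age+t1, t2)` holds to 1e-12.  Other-cause
death times invert the piecewise-exponential survival exactly (`S(T) = u`),
with an infinity sentinel when a finite horizon is exceeded.

National life tables are not redistributable, so the package bundles a
synthetic Gompertz-shaped "UK-like" generator: `r(a) = m_sex *
exp(-10 + 0.09 a)`, constant over calendar years, with a female multiplier
of 0.8.  At age 80 this gives 0.061/yr (men) and 0.049/yr (women),
comparable to recent UK national rates.  All tests and simulation studies
run against this table; estimator bias and coverage for the excess-hazard
parameters are insensitive to the exact background at these magnitudes, but
third-decimal agreement with results computed on the real national table is
not expected.

## Likelihood and inference

Both likelihoods drop the parameter-free population survival factor, so the
population term enters only through the rate at the observed exit time
(precomputed once per dataset — the cumulative background hazard is never
evaluated during optimization):

    classical:  sum_i [ delta_i log(hP_i + hE_i) - HE_i ]
    frailty:    sum_i [ delta_i log(hP_i + hE_i/(1 + b HE_i))
                        - (1/b) log(1 + b HE_i) ]

Optimization is over `log sigma, log nu, log gamma, alpha, beta, log b`,
removing all positivity constraints.  `b = 0` is not a boundary value of the
frailty model but a separate (classical) model compared by AIC; likelihood-
ratio testing of `b = 0` is deliberately unsupported because the statistic
is not asymptotically chi-square(1) at the boundary.  Non-finite likelihood
evaluations return a large negative constant so line searches back off
gracefully.

Fitting runs L-BFGS-B followed by a damped Newton polish using the
numerical Hessian (statsmodels `approx_hess`): the quasi-Newton stopping
rule is relative in `f` and can leave a gradient of order 1e-2 on
likelihoods of magnitude 1e4, while the polish brings the max-abs gradient
below ~1e-6, which the stationarity tests rely on.  The default
initialization mirrors the published recipe: fit the classical
proportional-hazards model first (neutral start: `sigma` = median event
time, `nu = gamma = 1`, `beta = 0`), then seed the full model with its
estimates, time-level effects starting at the PH hazard-level estimates and
`b` at 1.

Standard errors come from the inverse numerical Hessian on the transformed
scale.  Confidence intervals for positive parameters are formed on the log
scale and exponentiated (guaranteeing positive endpoints); coefficient
intervals are symmetric on the natural scale.  Reported natural-scale SEs
for positive parameters use the delta method (`se(p) = p * se(log p)`).
A fit is flagged non-convergent when the optimizer fails, the Hessian has
non-finite entries, or its inverse is not positive definite; the replication
harness excludes and counts such replicates.

Monte-Carlo net-survival intervals draw parameter vectors from
`N(psi_hat, J^{-1})` on the transformed scale (nearest-PSD eigenvalue
clipping if needed), recompute the population curve per draw, and report
pointwise quantiles.  When `b` is weakly identified (small samples, or data
without heterogeneity) its log-scale SE can be enormous and the upper band
approaches 1; this is a faithful reflection of the flat likelihood, not an
artifact.

## Synthetic-data generator

The generator reproduces the published simulation design.  Covariates: age
from a mixture of uniforms (0.25 on (30,65), 0.35 on (65,75), 0.40 on
(75,85)), standardized to mean 0 / SD 1 within each replicate (the design
does not say whether raw or standardized age enters; standardizing matches
the real-data analysis convention and is recorded here as the package's
choice); sex, X1, X2 Bernoulli(0.5) in Sc1.  Event machinery per
individual: a gamma frailty, a cancer time by exact GH inversion, an
other-cause time from the life table (sex mapping to the table stratum,
diagnosis year fixed at 2012 since the table is constant over years), an
exponential drop-out time, and administrative censoring at 5 years.  Status
is 1 iff a death (either cause) is the minimum; the latent cause and frailty
are kept for oracle tests.  Identical seeds give identical cohorts.

Drop-out rates are calibrated once by bisection on a 100 000-individual
pilot and frozen: 0.01965/yr gives ~5.0% drop-out in Sc1 (total censoring
~39-41%, against the published 40-45%; the small shortfall reflects the
lighter synthetic background mortality).  The two-subgroup scenarios
("close": sex-specific PGW baselines (0.5,1.5,5) vs (0.5,1.5,3); "far":
(0.5,1.5,5) vs (0.5,1.5,0.75); sex ~ Bernoulli(0.6); X1 | sex ~
Bernoulli(0.8/0.4); effects `alpha=(0.7,0.7,0.5), beta=(1,0.5,1)` for sex=1
and `alpha=(0.7,0.7,0.25), beta=(0.5,0.5,0.25)` for sex=0) target ~65%
total censoring, which requires rates 1.690 and 3.243/yr — in these designs
nearly all censoring is early drop-out, so 5-year curves lean on the
parametric extrapolation.  The published description gives three
coefficients for two generated covariates; the package reads the covariate
vector as (agec, sex, X1) with sex constant within each subgroup, so its
coefficient shifts the sex=1 baseline and is inert for sex=0.  No frailty is
placed in the two-subgroup truth: the unobserved heterogeneity there is the
omitted covariate X1 itself.  True subgroup curves are computed by
Monte-Carlo integration over 1e5 covariate draws (frailty, when present,
marginalized in closed form), giving MC error below 0.002 on the survival
scale.

What the generator does *not* emulate: real registries have measurement
error in life-table assignment, informative censoring, delayed ascertainment
and covariate missingness; passing tests on these synthetic cohorts shows
the estimator and its uncertainty quantification are correct under the
stated generating mechanism, not that the model fits any particular
registry.

## Replication harness and problem sizes

`run_replications` fits each simulated cohort (classical-PH initialization),
applies the exclusion rule, and tabulates mean/median MLE, bias, empirical
SD, mean estimated SE, and CI coverage per parameter.  The acceptance
experiments use M=200 replicates (Monte-Carlo SE of a coverage proportion
~0.015) at n=5000 and n=500; the AIC-selection experiment uses 20 seeds at
n=2000 with b=3; Aim-2 style curve comparisons in the test suite use n in
the 800-2000 range with ~6 replicates.  These are the package's desk-scale
defaults; all harness entry points accept arbitrary M and n.

Known behavior worth noting: at n=500 roughly a fifth of replicates have
the b MLE on the b -> 0 boundary (the log-scale optimizer drives log b to
very negative values on a flat likelihood).  Such fits are kept (their
transformed-scale Hessians are finite), which depresses the mean of b-hat
relative to the published small-sample bias figure — the mean of this
heavy-tailed, boundary-massed sampling distribution is very sensitive to
optimizer and exclusion conventions, while the median, coverage and
empirical SD reproduce the published pattern closely.

## Known limitations

* Additive hazard structures, spline baselines, exponentiated-Weibull and
  generalized-gamma baselines are out of scope.
* Shared or correlated frailties (e.g. on the population hazard, or
  life-table mismatch corrections) are not modelled.
* Profile-likelihood intervals and marginal/conditional AIC variants are not
  provided; model comparison is by plain AIC.
* The Pohar-Perme nonparametric net-survival estimator is not included;
  curves here are always model-based.
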