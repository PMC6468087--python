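# Methods

This note documents the statistical machinery in `fincr`: the likelihoods,
the conventions chosen where several are defensible, what the simulator
does and does not emulate, and the numerical details that matter for
reproducibility.

## Data model

An occasion is one field season, taken as a calendar year (seasons never
span a year boundary). A capture history is the binary vector
x_i = (x_{i1}, …, x_{iT}) with x_{it} = 1 iff individual i was identified
at least once in season t. Same-day duplicate sightings collapse to one
record on read, because capture is binary per occasion. Individuals whose
first-ever sighting is flagged as a calf are excluded entirely: a calf's
observation is conditional on its mother's presence and carries no
independent capture information. For the sexed subset, sex is known only
through biopsy; to avoid conditioning a history on a future event, a sexed
individual enters the data in its biopsy year and earlier sightings are
discarded. Every filter logs a count so printed sample sizes reconcile to
the input total.

## Site-fidelity indices and clustering

Two lifetime indices per individual, both with denominators starting at
the first sighting (inclusive):

- annual rate = (# years seen) / (# years from first sighting through the
  final year), so a rate of 1 means at least one identification every year;
- survey rate = (# distinct days seen) / (# survey days carried out since
  the first sighting).

When a day-level survey calendar is available (the simulator provides
one), the survey-day denominator counts days from the first sighting date;
with only per-year effort totals it falls back to whole-year totals from
the first-sighting year. Individuals first identified within the last five
years (configurable cutoff) are excluded — too little time has passed for
a stable index.

Both indices are standardized as (value − median)/MAD. The raw MAD is used
by default (`mad_constant` exposes the 1.4826 normal-consistency factor);
a zero MAD raises rather than silently switching scales. Clustering is
agglomerative under Ward's minimum-variance criterion with Euclidean
dissimilarity. Two variants are exposed because software differs: the
default is the squared-update Lance–Williams recurrence (scipy's `ward`,
R `hclust` ward.D2); `ward_d` applies the recurrence to unsquared
distances (R ward.D). Borderline individuals can switch groups between
variants, so published splits should not be expected to reproduce exactly
under either. The tree is cut at its top split (k = 2); the group with the
higher mean annual rate is labelled core-regular. Group comparisons use
the Welch unequal-variance t with Satterthwaite df and, for sex ratios, a
Pearson χ² with Yates continuity correction on the 2×2 table.

## CJS likelihood

Conditional on first capture f_i, the history contributes

- for each t in (f_i, l_i]: log Φ_{i,t−1} plus x_{it} log p_{it} +
  (1 − x_{it}) log(1 − p_{it}),
- after the last capture l_i: log χ_{l_i}, where
  χ_t = (1 − Φ_t) + Φ_t (1 − p_{t+1}) χ_{t+1}, χ_T = 1.

Trap-dependence makes p at t a function of capture at t − 1. Inside the
observed part this uses the observed history; in the χ recursion the first
step after the last capture uses the "previously captured" p (the animal
was captured at release) and all later steps the "not captured" p. With
this convention the conditional probabilities of all continuation
histories sum to 1 (verified by enumeration up to T = 6 at 1e−10).

Model structures are declared as formulas (`phi ~ T`, `p ~ t + m`,
`phi ~ s:T`, …) with an implicit intercept, treatment contrasts for time
factors, a standardized linear time index for T, and a cubic B-spline with
k interior knots at equally spaced quantiles for `spline(k)` (the
intercept-augmented basis sums to 1 at every interval; the knot count is
chosen by AICc over k = 1..6 when requested). `s:T` is the
one-slope-per-sex form: intercept + slope_F + slope_M, no sex main effect.
Parameter counts are the number of identifiable coefficients in this
parameterization; other software counts boundary-confounded parameters
differently, so npar columns are not comparable across programs.

In fully time-dependent models the final Φ and final p appear only as a
product; only that product is identified. Reported per-interval estimates
are population-average profiles: the weighted mean design row over
individuals defines the logit, with delta-method SEs from the coefficient
covariance and logit-scale 95% CIs (never real-scale Wald). For
trap-dependent models the p series is reported separately for m = 0 and
m = 1.

## Closed-form time-dependent estimators

The m-array yields the classical estimators: with m_t recaptures, R_t
releases, r_t later-seen and z_t seen-before-and-after-but-not-at t,
M̂_t = m_t + R_t z_t / r_t, p̂_t = m_t/M̂_t and
Φ̂_t = M̂_{t+1}/(M̂_t − m_t + R_t). These equal the numerical MLEs whenever
they are interior to (0, 1) — the test suite verifies agreement to 1e−6 —
and they serve as the fast route in replicated analyses. They are
unconstrained, so values slightly above 1 can occur in sparse data; the
logit-parameterized fit is then boundary-constrained and the identity no
longer applies.

## POPAN

The full open-population likelihood adds entry probabilities pent
(multinomial logit over occasions: constant = uniform with zero free
coefficients, T = one slope on the standardized occasion index, t = free
logits against the first occasion) and N through the never-detected term:
P0 = Σ_b pent_b ζ_b with ζ_t = (1 − p_t)[(1 − Φ_t) + Φ_t ζ_{t+1}]. N is
parameterized as D + e^η so the bound N ≥ D holds by construction; its CI
is log-normal on N − D. Transience is the standard covariate device — a
survival offset on the interval following first sighting — which makes the
observed-history probabilities conditional rather than generative, so the
probability-mass identity is checked for time-only structures.
Overdispersion ĉ estimated from the CJS-approximation GOF is passed in
(never recomputed inside the fit): it divides −2lnL in QAICc, counts as
one extra parameter (Burnham–Anderson convention, toggleable), and
inflates SEs by √ĉ. Model-averaged N uses QAICc weights with unconditional
variance and the same log-normal CI form. Effective sample size is total
releases over non-terminal occasions for CJS (the MARK convention) and
total captures for POPAN.

## Goodness of fit

Per-occasion 2×2 Pearson tables without continuity correction:

- Test3.SR: among animals seen at t, newly vs previously marked × ever
  seen again. Negative signed statistic = transience.
- Test3.SM: same split × next sighting at t+1 vs later.
- Test2.CT: among animals marked by t and seen after t, captured vs not
  captured at t × next capture at t+1 vs later. Positive signed statistic
  = trap-happiness (or sticky in-area presence under Markovian temporary
  emigration, which this component cannot distinguish).
- Test2.CL: the same conditioning among animals whose next capture is
  after t+1, timing t+2 vs later.

A 2×2 table cannot be pooled below 2×2 without destroying its contrast,
so tables with any expected cell below 2 (or a zero margin) are dropped
and contribute no df. The overall statistic is the sum of the four
components; ĉ = χ²/df. Under the homogeneous generative model both
headline components hold their nominal 5% level (empirically 0.050–0.055
over 1,000 replicates) and reach ≥ 80% power against 30% transients
(3.SR) and a +1.5 logit trap effect (2.CT) at the preset sample sizes.

## Terminal bias and truncation

Under Markovian (sticky) temporary emigration, animals that recently left
the area are disproportionately "missing" near the end of a series, which
depresses the final apparent-survival estimates — a bias that reaches
back over roughly the last one to three estimates, not just the last one.
`truncation_analysis` refits survival on histories truncated by several
seasons and compares the truncated series' terminal estimates with the
full-series estimates at the same years. The depression statistic is the
mean difference over the last three identifiable estimates (a
single-interval version is dominated by m-array sampling noise). Two
routes are provided: refitting the declared structure (default
Φ(t) p(t+m)) or the closed-form time-dependent estimators; replicated
analyses use the closed form, which is exact where interior and orders of
magnitude faster. The median survivorship summary is the median of the
model-averaged Φ̂ series, with the CI of the interval whose estimate is
closest to the median.

## Simulator

Each scenario draws N_super individuals; entry occasions follow pent;
each individual belongs to a latent fidelity class with its own survival,
2-state (in/out-of-area) Markov availability matrix, and detection
probability given alive-and-available; a transient fraction gets zero
survival on the interval after entry; detection responds to a logit trap
offset after a capture and to per-year logit effects; day-level sightings
within a season drive the survey index (one guaranteed day per capture
plus binomial extras at a class-specific rate). Death and emigration are
distinct latent events, so apparent survival = true survival × fidelity
can be checked against truth. Everything is driven by one
`numpy.random.Generator` seed; identical seeds give identical output.

Presets: `null_homogeneous` (single class, always available — the
calibration world), `transient_rich` (30% transients), `trap_happy`
(+1.5 trap effect), `markov_emigration` (sticky out-of-area state,
20 occasions), `two_cluster_fidelity` (two well-separated availability/
detection classes, ~30% core among clustered individuals, near-unit
survival in both classes so that lifetime indices express class identity
rather than mortality), and `gsl_like` (35 occasions, ~520 individuals,
28%/72% class mix, a late step increase in detectability mimicking the
switch to digital photography, 12% transients).

What the simulator does not emulate: spatially explicit movement,
continuous individual heterogeneity beyond the discrete classes,
misidentification, or effort-driven within-season variation. Passing
tests therefore demonstrate correctness of the estimators under the
stated generative assumptions, not robustness to every failure mode of
field data. In particular, the two-class scenarios deliberately violate
the homogeneity assumption of the POPAN model, and the fitted N̂ then
underestimates the true head count — the capture-heterogeneity bias this
workflow exists to expose; parameter-recovery assertions are made on the
homogeneous scenarios only.

## Numerical choices

Optimization is L-BFGS-B (ftol 1e−12, gtol 1e−8) with up to five jittered
starts from a seeded generator, followed by Newton polishing: with the
numerical Hessian (central differences, step 1e−4·(1+|θ|)) held fixed,
central-difference gradient steps are taken until the gradient norm
reaches the finite-difference noise floor (~1e−8). This brings fully
time-dependent MLEs within ~1e−9 of the closed-form estimators.
Coefficient covariance is the Hessian pseudo-inverse (pseudo because the
terminal CJS parameters can be confounded). Probabilities are clipped to
[1e−12, 1 − 1e−12] and linear predictors to ±30 inside likelihoods.
Identical histories (and covariate rows) are collapsed to weighted unique
rows before fitting. Residual deviance is reported against the saturated
multinomial on the reduced m-array and is exact only for models whose
likelihood is an m-array function (individual covariates break the
reduction; the value is then labelled approximate). Boundary estimates
(real parameters beyond 1 − 1e−4 or below 1e−4) set a flag on the fit
rather than failing.

## Known limitations

- The GOF pooling rule (drop sparse 2×2 tables) differs from U-CARE's
  multi-category pooling order, so exact χ²/df values from U-CARE are not
  expected to reproduce; the components' calibration and power are
  verified by simulation instead.
- npar counts are identifiable-coefficient counts; comparisons with other
  software's parameter columns are approximate (see above).
- The POPAN formulation models no pre-study entry distinctly: presence
  before the first occasion is absorbed into first-occasion entry mass.
- Per-occasion abundance N_t is not derived (only the super-population N).
- Sex enters models only as a two-level covariate on the sexed subset;
  unknown sex is never imputed.
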