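# Methods

## Study design and data model

The package models a binary-mixture developmental-toxicity study in
zebrafish embryos: three experiments (index chemical alone, co-chemical
alone, binary mixture), each with a control group T0 and five treatment
groups T1–T5, three replicate dishes per group and twenty embryos per
dish (360 fish per experiment). Measured concentrations (µg/L) drive all
analysis; nominal targets are kept as bookkeeping, and micromolar values
are a display conversion (`concentration / molecular weight`). The
universal data container is a per-fish table (pandas DataFrame) with
columns `experiment, replicate, treatment, alive, hatched, BL_mm,
SBA_mm2, YSA_mm2`; dead fish carry missing morphometrics.

## Synthetic-data generator

Continuous endpoint means follow a line in the potency-weighted total
dose `w·C` (index weight 1, co-chemical weight defaulting to 1/13.88, the
limiting potency ratio of the reference component fits), with Gaussian
per-fish noise truncated at zero, since lengths and areas cannot be
negative. Mortality and hatching are per-group Bernoulli draws — these
endpoints were essentially unresponsive over the dose ranges of interest,
so flat default rates (5% mortality, 90% hatch) are used rather than
dose–response functions. Defaults for the swim-bladder endpoint are the
reference component fit (intercept 0.04563 mm², slope −6.45×10⁻⁶ mm² per
µg/L, fish-level SD 0.013 mm²); body length (3.9 mm, SD 0.15) and yolk
sac area (0.20 mm², SD 0.03) carry weak trends chosen to be realistic for
5-dpf larvae. Controls default to zero dose; the measured 1.9 µg/L
6:2 FTS carryover in one control can be re-enabled
(`include_control_trace=True`), and design validation tolerates control
traces up to 1% of the top dose.

What the generator does **not** emulate: dose-dependent mortality,
between-replicate (dish) random effects, measurement error correlation
among endpoints within a fish, and chemical mass-loss over the exposure.
Passing recovery/coverage tests therefore demonstrate correctness of the
estimators under clean design assumptions, not robustness to those
real-data features.

One caveat the zero-truncation creates deliberately: at the top reference
PFOS dose (7475 µg/L) the true line approaches or crosses zero, so
simulated top-group means sit above the line and flatten fitted slopes.
Parameter-recovery and coverage checks therefore fit over the control–T4
range, exactly the dose range over which a linear model is a sensible
description — the analysis of the real data likewise excluded the
non-monotone top group.

## Dose–response fitting and benchmark doses

All candidate models are fitted to individual fish pooled across
replicates (not replicate means) under constant residual variance, by
normal maximum likelihood; AIC = 2k − 2ℓ counts the variance among the k
parameters. Linear and quadratic fits are closed-form least squares; the
power, three-parameter exponential and Hill models use bounded L-BFGS-B
with multiple shape starts, with the shape/steepness exponent restricted
to [1, 18] to exclude infinite-slope low-dose pathologies. Non-converged
models are reported with a failure status, never silently dropped.

The benchmark response is a shift of the mean equal to `bmr_sd` (default
1) control-group standard deviations in a per-endpoint adverse direction
(decrease for swim bladder area and body length, increase for yolk sac
area). The BMD is the smallest positive dose reaching that shift; if the
shift is not reached within 10× the maximum fitted dose the result is a
typed `no_solution`. The BMDL is the one-sided 95% profile-likelihood
bound using the χ²₁ 90% two-sided cutoff (the usual BMDS convention):
analytic for the linear model (the profile deviance is
`n·log(RSS(b)/RSS(b̂))`, quadratic in the slope), and a
bisection-over-BMD with an SLSQP equality-constrained inner fit for the
others, run in a normalised parameter space because raw parameters can
span ten orders of magnitude. If profiling fails, a delta-method bound on
log(BMD) is used and flagged in `bmdl_method`. Each result carries the
scaled residual at the dose group nearest the BMD and a
`questionable_extrapolation` flag when the BMD is more than 3-fold below
the lowest nonzero dose. A constant-variance likelihood is an explicit
choice; dose-dependent variance modelling is out of scope.

A screening rule (`exclude_nonmonotonic_top`) drops the highest dose
group if and only if its step from the second-highest group opposes the
overall trend direction by more than one control SD; the decision is
logged.

## Points of departure

ANOVA and Tukey HSD run on replicate means (n = 3 per group), matching
how such studies are analysed; this is deliberately low-powered and the
type-I behaviour of the whole pipeline is verified by simulation (the
familywise-corrected any-contrast false-positive rate over 1000 null
studies must lie in [0.01, 0.10]). The LOAEL is the lowest significant
dose and the NOAEL the highest dose below it; significance at the lowest
dose makes the LOAEL unbounded-low, no significance anywhere makes the
top dose an unbounded-high NOAEL. Non-monotone significance patterns
(significant mid-dose, quiet top dose) keep the lowest-significant-dose
rule and log a warning rather than fail. POD ratios propagate qualifiers:
an unbounded-low ("<") numerator or unbounded-high (">") denominator
yields an upper bound, the mirror cases a lower bound, agreeing
directions are `indeterminate`, so the algebra is total. Reported ratios
round to two significant figures; full precision is kept internally.

## Percent response and relative potency

Percent response is anchored to the **observed control mean** R₀, not the
fitted intercept: `p(D) = 1 − (a + bD)/R₀`. Because fitted intercepts sit
below the control means in these data, p(0) > 0 (≈28% for the reference
PFOS fit), and response levels below that baseline have no positive-dose
solution; such levels return a typed `below_intercept` status, never a
negative dose. The inverse `D(p) = (R₀(1 − p) − a)/b` is exact and is
property-tested as the round-trip inverse to 1e-9. The co/index dose
ratio varies monotonically in the response level (direction given by the
sign of `R₀ᵢaᶜ − R₀ᶜaᵢ`) and converges, as the response approaches 100%,
to the ratio of x-intercepts `(aᶜ/|bᶜ|)/(aᵢ/|bᵢ|)` — the "limiting
relative potency". The default response grid is 0.20–0.90 in steps of
0.10.

## Mixture analysis

Two additivity notions are implemented and named, because both are needed
and they are not interchangeable:

- **Dose addition** (Loewe): isoboles join the two single-chemical
  iso-effective doses at one response level (shared code path with the
  relative-potency inversions). Observed mixtures below the line respond
  more than additively.
- **Response addition**: the predicted mixture response sums each
  component's percent response at its concentration, flooring components
  at 0 and capping the sum at 100% (sums above 100% are otherwise
  meaningless).

The five-step balance procedure runs per response level: index-alone dose
→ index-in-mixture dose → balance (difference) → co-chemical-in-mixture
dose → relative potency = balance / co-dose. Non-positive balances are
flagged `antagonistic` (the mixture needed more index chemical than the
component study, including the zero-balance boundary case) and excluded
from ratios; levels below any involved intercept are flagged
`below_intercept`.

**Baseline-convention caveat.** The control-mean baseline is used
uniformly. For the reference top-dose mixture point (PFOS 1570 µg/L,
6:2 FTS 15,229 µg/L, observed 51% reduction) the uniform control-mean
prediction is ≈44% + 22% = 66%, so response addition *over*predicts and
the point reads antagonistic; only under an intercept-anchored baseline
(≈22% + 16% = 38%) does the observation exceed the prediction and read
synergistic. Published discussions of this design mix the two
conventions, which is why `classify_point` exposes
`baseline="control_mean" | "intercept"` and the additive-call tolerance
defaults to ±0.05 absolute response (a ~7-point difference is at the edge
of what such a design can resolve). The dose-addition isobole view is
unaffected by this ambiguity.

## Numerical and reporting choices

- Seeded numpy PCG64 generator throughout; the seed is recorded in table
  metadata and report headers (with package version and a config hash).
- BMD root-finding brackets the *first* crossing on a 400-point geometric
  grid before Brent refinement, so polynomial fits that turn upward far
  beyond the data do not mask an interior solution.
- Doses report to 4 significant figures, ratios to 2–3, rounding applied
  only at output.
- Degenerate inputs are typed errors: single-dose designs, zero slopes,
  zero/negative PODs, invalid probabilities, negative concentrations.

## Problem sizes used in the test-suite simulations

Parameter recovery and CI coverage use 500 simulated studies (5 groups ×
3 × 20 fish); the null-calibration check uses 1000 simulated ANOVA
pipelines; the bootstrap oracle for the profile BMDL uses 2000 stratified
case resamples of one 300-fish study. These sizes give Monte-Carlo error
comfortably inside the asserted acceptance bands.

## Known limitations

- Continuous endpoints only; no dichotomous BMD models, no model
  averaging, no BMDS file compatibility.
- Mixtures of exactly two components; no toxic-equivalency scaling across
  a wider PFAS panel.
- The replicate-means ANOVA has very low power at n = 3; it is faithful
  to practice, not optimal.
- No estimation of where the interaction transitions between less- and
  more-than-additive; the design cannot resolve that inflection point.
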