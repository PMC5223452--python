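# Methods

## Model and estimation

Each item *j* carries known instrument bounds (minⱼ, maxⱼ); observed
responses are rescaled affinely, xₙⱼ = (oₙⱼ − minⱼ)/(maxⱼ − minⱼ), onto
[0, 1]. A rescaled cell is treated as a *fractional success*: its model
expectation is the one-parameter Rasch probability pₙⱼ = σ(θₙ − δⱼ) with
σ the logistic function, and its working variance is the binomial form
pₙⱼ(1 − pₙⱼ). No full likelihood for continuous cells is assumed; the
estimating equations are the quasi-binomial score equations

    Σⱼ (xₙⱼ − pₙⱼ) = 0  for every person n,
    Σₙ (xₙⱼ − pₙⱼ) = 0  for every item j,

whose Newton updates are exactly the person and item steps implemented
(step = ΣR/ΣVar). For binary data these are the classical joint-ML (JMLE)
equations, which is what makes the dichotomous validation path meaningful.

All parameters start at 0 logits. One outer iteration is: person half-step →
refresh expectations → item half-step → re-center difficulties → refresh
expectations. The order (persons first) is a fixed convention; the
alternative converges to the same fixed point and is covered by the oracle
cross-check. Difficulties are re-centered to mean zero *every* iteration
(the logit scale is translation-invariant, so the constraint is pure
identification and does not move the fit).

Stopping: total absolute residual Σ|O − E| < `convergence_tol` (default
0.01) — reachable only for near-noiseless data — or largest parameter change
< `change_tol` (default 1e-4), or `max_iter` (1000), which warns and returns
`converged=False` rather than raising. A parameter-change criterion is
needed because for misfitting data the residual sum has a strictly positive
floor.

### Numerical safeguards

- **Damping**: raw Newton steps are capped at `max_step` = 1 logit. Far from
  the solution the quadratic approximation overshoots; near it the cap is
  inactive, so convergence is unimpeded.
- **Clamping**: estimates live in ±`theta_clamp` = 10 logits. Extreme
  response strings (every observed cell at a scale bound) have divergent ML
  estimates; they are flagged, drift to the clamp, and are excluded from the
  centering constraint so they cannot shift the scale origin. Their cells
  still enter the opposite margin's sums (the update formulas are applied
  verbatim; at the clamp their variances are tiny, so the influence is
  negligible).
- **Variance floor** 1e-6 keeps denominators and standardized residuals
  finite as p → 0 or 1.
- Missing cells are excluded from every sum; row/column denominators use
  observed counts.

Standard errors are the usual Rasch asymptotics, SE = 1/√(ΣVar) over a
person's (item's) observed cells — interpretable as such only to the extent
the quasi-binomial variance describes the data (see Limitations).

## Fit statistics

Z = R/√Var is kept *signed* (the familiar definition is the root of a
square, which would lose direction); diagnostics need the sign to separate
strengths (Z ≥ +2) from weaknesses (Z ≤ −2). OUTFIT is the unweighted mean
of Z² per row/column, INFIT the variance-weighted ratio ΣR²/ΣVar; with
constant variance they coincide identically. Misfit thresholds — item
INFIT 1.5, person OUTFIT 2.0, |Z| 2.0 — are the conventional screening
levels; flags are closed at the boundary (≥), a documented convention since
the acceptable side is usually phrased as "less than".

Continuous responses concentrate far more tightly around pₙⱼ than a
Bernoulli draw would, so raw mean squares on CIR data sit well below the
nominal expectation of 1. `normalize_mnsq` divides each set (person INFIT,
person OUTFIT, item INFIT, item OUTFIT) by its own mean so the conventional
0.5–1.5 interpretive band applies; flags are then computed on the normalized
values. Normalization is off by default because on dichotomous data the raw
statistics are already calibrated (the suite checks the grand-mean OUTFIT of
a correctly specified binary simulation lies in [0.85, 1.15]).

R² is Σ(E − X̄)²/Σ(X − X̄)² over observed cells with X̄ the grand mean of the
observed rescaled responses (a per-item-mean variant is available via
`center="item"`; the choice matters little when items share a common
range). An F statistic is provided with df (1, n_cells − 2), the df of a
single-predictor regression of observed on expected values, since the ratio
alone does not determine a test. The two-item difficulty comparison uses
t = (δₐ − δ_b)/√(1/ΣVarₐ + 1/ΣVar_b) with a standard-normal two-sided tail —
the large-sample reference distribution; no small-sample df correction is
attempted.

## Diagnostics

Builders are pure functions from a fit to plain data structures; JSON is the
canonical, testable surface and SVG/PNG rendering is presentation only.
The Wright map bins non-extreme person measures at 0.25-logit width (a
display default; bin totals are conserved under any width) and pairs each
item with its INFIT so unidimensionality can be read off one panel. KIDMAP
cohort boxes are five-number summaries (min, Q1, median, Q3, max; quartiles
by linear interpolation) because no single whisker convention is canonical
for bounded responses. The ICC overlay plots persons at (measure, OUTFIT)
with a reference line at 2.0; the vertical axis is the fit statistic alone —
mixing a second response axis into the same panel is exactly the kind of
two-axis display that confuses readers.

## CAT engine

Selection maximizes Rasch information p(1 − p) at the provisional measure —
equivalently, picks the unadministered item nearest in difficulty; ties go
to the lowest bank index. The provisional measure solves the score equation
over administered items by damped Newton from the previous value (so a
one-item session gives the closed form θ = logit(x)). Session diagnostics:
MSE = 1/√(ΣVar); `resi` = mean of the last three absolute measure changes,
defined once four estimates exist; `corr` = Pearson correlation of the last
three measures with their step numbers, display-only (a flat trend suggests
convergence, but only `resi` stops the session). The stop rule is strict:
resi < 0.05. Its own precondition imposes a four-item minimum. The item bank
is Rasch-only — every discrimination is 1 by construction; graded-response
parameterizations are out of scope. Initial measure 0; `max_items` defaults
to the bank size.

## Synthetic data

The generator emulates a bounded-continuous survey: person measures
N(mean, sd) (default standard normal — the typical spread of a calibrated
logit scale), difficulties explicit or equally spaced in [−1, 1] and always
mean-centered, and three cell-noise modes. Beta noise is parameterized by
mean and precision, x ~ Beta(pν, (1 − p)ν), so the Rasch expectation is
preserved *exactly* and the variance is p(1 − p)/(ν + 1); precision ν = 12
gives cell scatter (sd ≈ 0.1 at mid-scale) of the order seen in per-unit
domain scores. Exact mode (x = p) gives the noiseless identifiability check;
binary mode gives classical Rasch data.

What the simulations do not emulate: real multi-domain surveys have
correlated residuals across domains, non-beta (often ceiling-skewed)
noise, and respondent-level aberrance; passing recovery and calibration
tests under the generator shows the estimator is correct under its own
model, not that any particular instrument fits it.

The estimation oracle is deliberately primitive: coordinate ascent on the
fractional-success log-likelihood, one parameter at a time by golden-section
search (derivative-free, bracket ±12 logits, tolerance 1e-8 per search),
with the translation ridge fixed by re-centering δ and shifting θ by the
same amount after each sweep, until the largest per-sweep change is below
1e-6. It shares no code or calculus with the Newton fit, which is what makes
the ≤ 0.02-logit agreement test on a 100 × 11 dichotomous matrix (extreme
rows/columns stripped first, since neither estimator is defined there) a
genuine cross-validation of both.

## Problem sizes and determinism

Test and acceptance computations use 80–500 persons and 6–30 items — the
scale of the motivating survey applications — and finish in seconds. Every
stochastic component flows through an explicit integer seed
(`numpy.random.default_rng`); property tests are derandomized. The
200-session CAT coverage check uses beta respondents at ν = 12 against a
30-item bank equally spaced in [−2, 2]; note the engine's MSE assumes
quasi-binomial cell variance while beta noise at ν = 12 is ~13× tighter, so
the nominal 95% interval is conservative and observed coverage approaches
100% — the ≥ 85% bound tests the direction of that conservatism, not
interval exactness.

## Known limitations

- The quasi-binomial variance overstates the scatter of genuinely continuous
  responses; raw mean squares and standard errors inherit that mismatch
  (hence `normalize_mnsq`, and the conservative CAT intervals above).
- Joint (person-and-item) estimation carries the usual finite-length bias of
  JMLE on short tests; no (L−1)/L-style correction is applied.
- Only a difficulty parameter is modeled: no discrimination, no guessing,
  no integer-format rating-scale machinery, and no conditional or marginal
  ML alternatives.
- Instruments whose items lack a shared, meaningful bounded scale (e.g.
  heterogeneous laboratory panels) need a standardization step that is out
  of scope here; per-item bounds must be scientifically meaningful for the
  rescaling to be.
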