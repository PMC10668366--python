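# Methods

## Model and hypotheses

Two independent arms, control `x` and experimental `y`, with Normal residuals
and a common population variance σ².  All hypotheses are placed on the
standardized effect size δ = (μₑ − μ꜀)/σ.  The two model components are:

* **Effect size prior.**  Under the alternative, δ ~ Cauchy(0, r).  The
  scale r fixes the width: half the prior mass lies in (−r, r).  The default
  r = 1/√2 matches the default of the widely used Bayes-factor tools for
  t designs.  One-sided hypotheses use the same center-0 Cauchy truncated to
  the half-line and renormalized; this includes non-inferiority, where the
  prior is Cauchy(0, r) restricted to δ > −c, so the truncation sits exactly
  at the point null.  (An alternative construction centers a half-Cauchy at
  the margin itself; the two disagree for c > 0 and this package deliberately
  uses the center-0 truncated form, which is also the form whose Savage–Dickey
  ratio at the boundary equals the marginal-likelihood ratio.)
* **Nuisance variance.**  σ² carries the Jeffreys (right Haar) prior
  p(σ²) ∝ 1/σ² and the common location a flat prior.  Both are integrated out
  analytically, which is exact: the sampling distribution of the pooled
  two-sample t statistic given δ is noncentral t with df = nₓ + n_y − 2 and
  noncentrality δ·√n_eff, n_eff = nₓn_y/(nₓ + n_y).  The engine therefore
  never grids or samples σ².

Bayes factors:

* superiority (BF₁₀): ∫₀^∞ f(t | δ) π(δ) dδ / f(t | 0) with the half-Cauchy π.
* non-inferiority (BF₁₀): ∫₋꜀^∞ f(t | δ) π꜀(δ) dδ / f(t | −c) with π꜀ the
  center-0 Cauchy truncated to δ > −c.
* equivalence (BF₀₁), point null {0} (the default): the Savage–Dickey density
  ratio posterior(0)/prior(0) under the full Cauchy model, which reduces
  exactly to f(t | 0) / marginal.
* equivalence (BF₀₁), interval (−c, c) or asymmetric (l, u): posterior odds of
  the interval against its complement divided by the prior odds, both under
  the single untruncated center-0 model.

Direction handling: inputs are canonicalized once at the boundary — with
`direction="low"` the observed mean difference is negated — so that larger δ
is always favorable internally.  Equivalence is direction-free.

## Input modes and data reduction

1. raw vectors → means, (n−1)-denominator SDs;
2. per-arm n, mean, SD → pooled-SD two-sample t;
3. per-arm n and mean plus a CI for the mean difference: the half-width is
   divided by the central Student-t quantile at (1 + level)/2 with
   nₓ + n_y − 2 df to give the standard error, and the pooled SD is recovered
   as se/√(1/nₓ + 1/n_y) for margin standardization.

Margins supplied in outcome units are divided by the pooled SD.  Degenerate
inputs (n < 2, zero pooled variance, inverted interval bounds, negative
margins, confidence levels outside (0, 1)) raise errors; nothing is coerced
silently.

## Numerics

* **Noncentral-t log-density.**  `scipy.stats.nct` overflows for large df
  combined with large noncentrality (internal gamma-function blowup), which is
  precisely the regime of decisive data (the worked example needs
  f(t = 9.3 | df = 396, nc ≈ −10)).  The engine therefore evaluates the density
  through the chi-square mixture representation
  f(t; ν, nc) = E_W[s·φ(st − nc)], s = √(W/ν), W ~ χ²_ν, as a trapezoid sum on
  log W over the 10⁻¹²⁰–(1 − 10⁻¹²⁰) quantile range with 4096 nodes, entirely
  in log space.  The decaying smooth integrand makes the trapezoid rule
  effectively spectrally accurate; agreement with `scipy.stats.nct.logpdf` in
  the moderate regime is ~10⁻¹³, and the very wide quantile range matters in
  deep-tail point-null evaluations (cutting at 10⁻¹⁸ quantiles produced
  ~7·10⁻⁴ log errors at df = 396, t = 10).  The per-(t, df) grid is cached so
  repeated δ evaluations inside a quadrature cost one vectorized pass.
* **Marginal likelihoods.**  ∫ f(t | δ) π(δ) dδ is computed on the
  arctangent-compactified axis u = atan((δ − center)/scale), where the Cauchy
  weight becomes the flat measure du/π and the heavy tails are controlled.  A
  coarse 2001-point scan locates the integrand maximum (subtracted before
  exponentiation, so Bayes factors of any magnitude stay finite) and supplies
  breakpoints to `scipy.integrate.quad` (relative tolerance 10⁻¹⁰, accepted
  error 10⁻⁸); on warning or insufficient accuracy the engine falls back to a
  dense 50001-point trapezoid over the whole compactified support.  Interval
  masses reuse the same routine on sub-intervals; interval-vs-complement odds
  are formed from the two integrals directly rather than via 1 − mass, so
  nothing cancels catastrophically.
* **All BF arithmetic in natural-log space**; orientation flips are sign
  negations, exactly.

## The reference oracle

`oracle_log_marginal` / `oracle_log_bf` recompute every Bayes factor by
brute-force integration of the raw-data Normal likelihood over (δ, log σ²):
the common location is integrated analytically (a one-dimensional Gaussian
integral), the Jeffreys measure is flat in log σ², and both remaining
dimensions are handled by trapezoid sums on explicit composite grids — dense
around the likelihood peak, the prior center, truncation bounds and interval
edges, coarse in the far tails (±300 prior scales).  The oracle shares no
integration code or parameterization with the engine (explicit variance grid
versus analytic noncentral-t reduction), so their agreement — |Δlog BF| well
below 10⁻³ across a 54-case grid spanning t ∈ [−10, 10], df ∈ {4, 30, 396},
r ∈ {1/√2, 1} and margins {0, 0.5, 1} — certifies the engine.  The improper
prior constants cancel in every Bayes factor; oracle marginals are therefore
only compared as differences.  Grid halving moves oracle values by < 10⁻⁴.
The oracle is deliberately slow and lives in the package only for the test
suite and the acceptance script.

## Frequentist companions

Superiority: one-sided pooled t-test.  Non-inferiority: one-sided test of the
shifted statistic t + c√n_eff.  Equivalence: the two one-sided tests (TOST)
against the interval bounds, rejecting non-equivalence iff
max(p_lower, p_upper) < α (default α = 0.05).  With a standardized margin the
shift uses the estimated pooled SD, the standard practice for summary-data
TOST; the suite cross-checks against `statsmodels.stats.weightstats.ttost_ind`.

## Reporting conventions

Bayes factors print in scientific notation with 3 significant digits when
|log₁₀ BF| ≥ 4 and with 2 decimals otherwise; the orientation (evidence
towards null or alternative) is always stated in brackets.  Evidence-strength
labels use thresholds 3 / 20 / 150 on max(BF₁₀, BF₀₁): "not worth more than a
bare mention", "positive", "strong", "very strong", with the favored
hypothesis named.  Reports are pure functions of their inputs (byte-stable);
timestamps appear only in logging on standard error.

## Design choices and limitations

* The interval-null equivalence BF converges to the point Savage–Dickey value
  as the half-width ε → 0, but only linearly (leading error
  2ε·|posterior − prior density at 0|); the tests assert the rate, not a
  spuriously tight limit.
* Test problem sizes: the certification grid uses equal arms of 3, 16 and 199
  (df 4, 30, 396), which brackets desk-scale and trial-scale designs; the
  noncentral-t reduction is exact in n, so small-n certification carries over.
* No Monte Carlo anywhere in the engine; the package needs no seeds.
* Out of scope: Welch-type unequal-variance models, binary endpoints,
  informed non-central priors beyond center/scale/truncation, credible-
  interval (ROPE) decision rules, and multi-arm designs.
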