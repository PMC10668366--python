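# trialbf

Bayes factor hypothesis tests for the three two-arm designs that dominate
clinical and biomedical comparisons of a continuous outcome:

* **superiority** — is the experimental arm better than control?
* **equivalence** — are the two arms practically interchangeable?
* **non-inferiority** — is the experimental arm *not worse* than control by
  more than a pre-specified margin?

Classical analyses of these designs report p-values, which cannot quantify
evidence *for* a null hypothesis and force rigid sampling plans.  The Bayes
factor BF₁₀ = p(D | H₁) / p(D | H₀) answers the question directly: it is the
factor by which the data shift the prior odds of the hypotheses, whichever
hypothesis they favor.

## Model

Both arms are modeled as Normal with a common variance; hypotheses are stated
on the standardized effect size

δ = (μₑ − μ꜀)/σ.

Under H₁, δ receives a Cauchy prior with location 0 and scale *r* (default
*r* = 1/√2, so half the prior mass lies in (−*r*, *r*)), truncated to the
relevant side for the one-sided designs.  The nuisance variance σ² carries
the Jeffreys (right Haar) prior p(σ²) ∝ 1/σ² and is integrated out
analytically, so the likelihood of the observed two-sample t statistic is
noncentral t with noncentrality δ·√(nₓn_y/(nₓ+n_y)).  The hypotheses are

| design          | H₀              | H₁              | reported |
|-----------------|-----------------|-----------------|----------|
| superiority     | δ = 0           | δ > 0           | BF₁₀     |
| equivalence     | δ ∈ (−c, c) or δ = 0 | δ outside  | BF₀₁     |
| non-inferiority | δ = −c          | δ > −c          | BF₁₀     |

where *c* is the standardized margin (margins given in outcome units are
divided by the pooled SD).  Point-null Bayes factors use marginal-likelihood
ratios (equivalently the Savage–Dickey density ratio); interval nulls use the
ratio of posterior to prior odds of the interval under the untruncated
center-0 model.  A `direction` flag states whether high or low outcome scores
are favorable; internally everything is canonicalized so that larger δ is
better.

Data can enter three ways: raw outcome vectors per arm; per-arm sample sizes,
means and SDs; or sample sizes and means plus the half-width and level of a
confidence interval for the mean difference.

## Worked example

A large trial compared flexible versus standard duty-hour programs for
medical trainees on a 9-point sleepiness scale (lower is better), asking
whether the flexible program is non-inferior with a margin of 1 point.
Summary statistics: n = 193 (standard) and 205 (flexible), means 4.7 and 4.8,
and a 95% CI for the mean difference with half-width 0.19.

```python
import trialbf as tb

out = tb.noninferiority_test(
    n_x=193, n_y=205, mean_x=4.7, mean_y=4.8,
    ci_margin=0.19, ci_level=0.95,
    ni_margin=1.0, ni_margin_std=False, direction="low",
    frequentist=True,
)
print(out.report())
```

prints

```
Bayesian non-inferiority test
=============================
Data: summary statistics (means and CI for the difference)
Groups: control n = 193, experimental n = 205
H0: delta = -1.038 (worse by exactly the margin)
H1: delta > -1.038 (non-inferior)
Cauchy prior scale: 0.707107
Non-inferiority margin (standardized): 1.0378
BF10 [evidence towards the alternative hypothesis] = 8.56e+17
Evidence: very strong (towards H1)
Frequentist: t(396) = 9.313, p < 0.001 -> reject H0 at alpha = 0.05
```

The 1-point raw margin becomes a standardized margin of 1.038 after dividing
by the pooled SD recovered from the confidence interval.  The data are about
8.6 × 10¹⁷ times more likely under non-inferiority than under the hypothesis
that the flexible program is worse by exactly the margin — decisive evidence,
in line with the trial's frequentist conclusion (p < .001).

The same analysis from the shell:

```sh
trialbf --design noninferiority \
    --n-x 193 --n-y 205 --mean-x 4.7 --mean-y 4.8 \
    --ci-margin 0.19 --ci-level 0.95 \
    --ni-margin 1 --direction low --frequentist
```

`--json` emits a machine-readable result and `--export-curves curves.csv`
writes the prior/posterior density curves (with the null-point densities as
metadata, so the Savage–Dickey ratio can be recomputed from the file).

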