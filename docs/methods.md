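# Methods

## The model

The package analyses gene-by-environment (GxE) interactions of the
crossover form

    Y = b0 + b1·X + b2·Z + b3·X·Z + e,        e ~ N(0, σ²)

where `Y` is a continuous anxiety-spectrum outcome (e.g. a neuroticism or
social-anxiety scale total), `X` is a continuous environment score — the
mean subjective impact of recent life events on a −3 (extremely negative)
to +3 (extremely positive) scale — and `Z` is a binary genetic moderator
(0 = non-risk reference group, 1 = risk-allele or risk-haplotype
carriers). Fitting is ordinary least squares with the classical
homoskedastic coefficient covariance; this matches the era-standard
output of the statistical packages such study designs were analysed
with, and no robust/sandwich correction is applied. Two-sided t tests at
α = 0.05 are used throughout, with no multiple-testing correction — a
deliberate property of the analysis design, not an omission.

`X` enters **uncentered** by default. The crossover point −b2/b3 and the
published coefficient tables this package can reproduce live on the raw
environment scale; had the environment been centered, b2 (and hence the
crossover identity) would change. Centering is available as an explicit
opt-in that re-expresses the model; it is never applied silently.

### Simple slopes

The environment effect at each moderator level is `b1` (Z = 0) and
`b1 + b3` (Z = 1), with `var(b1 + b3) = var(b1) + var(b3) + 2 cov(b1, b3)`
and t intervals on the model's residual df.

### Nonlinearity check

A significant linear interaction can mask a nonlinear environment
effect, which would undermine a differential-susceptibility reading. The
augmented model adds `X²` and `X²·Z`; the "nonlinearity detected" flag is
driven by the joint F-test of the two terms at α (both individual
p-values are reported alongside). The joint test was chosen as the single
decision rule because it controls the error rate of the combined
question; under a purely linear generative model it flags at its nominal
5% rate.

### Covariate-interaction (Keller) adjustment

Testing a GxE term while adjusting covariates only as main effects can
leave the interaction confounded through covariate-by-environment or
covariate-by-gene pathways. The adjusted model therefore enters, for each
covariate C, the terms `C`, `C·X` and `C·Z` (no three-way `C·X·Z`), and
reports the GxE p-value from that expanded model.

### Auxiliary checks

* Gene-environment correlation: pooled-variance two-sample t-test of X
  across moderator groups, with Cohen's d and a normal-approximation CI —
  a significant association would make the interaction uninterpretable.
* Environment normality: Shapiro-Wilk (required because the PA index
  assumes a normal environment distribution).
* Hardy-Weinberg conformance per SNP: 1-df chi-square without continuity
  correction (conformance is the claim being checked; an exact test is
  unnecessary at these sample sizes and effect structure).

## Susceptibility indices

All indices are computed over an evaluation range conventionally set to
the environment mean ± 2 SD (computed from the analysed sample, with an
explicit override available for reproducing published tables computed on
a fixed printed range).

* **Crossover** `xc = −b2/b3`: the environment value at which the two
  group lines intersect. Requires b3 ≠ 0; a vanishingly small b3 relative
  to b2 triggers a warning since the crossover then sits far outside any
  plausible range.
* **Regions of significance on X** (Johnson-Neyman): the x values where
  the group difference `b2 + b3·x` reaches significance solve
  `(b2 + b3 x)² = t²_{α/2,df} (var(b2) + x² var(b3) + 2x cov(b2, b3))`,
  a quadratic in x. The difference is significant outside the two roots.
  A side counts as significant when its region intrudes into the
  evaluation range. When the quadratic degenerates (no real roots, or a
  non-significant b3 flipping the parabola), side significance falls back
  to direct pointwise tests at the range endpoints and the bounds are
  reported as absent.
* **PoI** (Proportion of Interaction): the share of the total area
  between the two group lines lying on the *for-better* side of the
  crossover. For straight lines each side's area is a triangle, so the
  right-side share reduces to
  `(x_upper − xc)² / [(x_upper − xc)² + (xc − x_lower)²]`; a crossover at
  or beyond a range edge clamps the index to 0 or 1 (and classification
  then cannot be differential susceptibility). The for-better side is
  derived from the outcome polarity and the sign of b3: with a
  higher-is-worse outcome and b3 < 0, risk carriers fare better than the
  reference group to the right of the crossover. All published fits this
  package reproduces have that configuration; the rule keeps the index
  meaningful for mirrored data.
* **PA** (Proportion Affected): the share of individuals on the
  for-better side of the crossover under a normal model for X:
  `1 − Φ((xc − mean)/sd)` when the for-better side is the right side.
* **Pattern label**: differential susceptibility iff both sides are
  significant, 0.40 ≤ PoI ≤ 0.60 and PA > 0.16; diathesis-stress iff only
  the negative-environment side is significant and PoI < 0.40; vantage
  sensitivity iff only the positive side is significant and PoI > 0.60;
  otherwise inconclusive (all component verdicts are retained). Rows
  whose interaction is not significant get "no_interaction" and no
  indices, unless index computation is explicitly forced.

Published PA values for this family of analyses are generally *not*
reproducible from the reported environment mean/SD with the normal-CDF
definition (the web tools involved appear to have used the unavailable
empirical distribution), and published region-of-significance boundaries
require the unreported coefficient covariance. PA is therefore validated
by its analytic properties (0.5 at the mean, standard normal tails,
monotone in the crossover), and RoS boundaries against a grid-search
oracle — not against printed values.

## Genetics preliminaries

Risk-carrier moderators are built from biallelic genotypes coded as
risk-allele dosages. Dominant coding contrasts non-risk homozygotes with
carriers of ≥ 1 risk allele; missing genotypes are excluded listwise per
analysis (so the analysed n can differ between SNP and haplotype
moderators).

Haplotype frequencies over the three-SNP block are estimated by EM on the
multinomial likelihood under random union of haplotypes, replacing the
Bayesian phasing software used historically; for three tight SNPs the
likelihood surface is benign and EM with one uniform start plus ten
seeded Dirichlet restarts (deterministic given the seed) reliably finds
the maximum. The per-iteration log-likelihood is non-decreasing by
construction and is exposed for verification. Each individual is assigned
the posterior-argmax diplotype (ties broken lexicographically by
haplotype string); the haplotype moderator codes carriers of the risk
haplotype as 1, carriers of the reference haplotype (without a risk copy)
as 0, and excludes individuals with neither. Pairwise D′ and r² are
computed from the marginalized joint haplotype frequencies.

## The synthetic-data generator

The generator emulates the study conditions the analysis assumes:

* n = 86 individuals by default; five SNPs, of which three form a
  haplotype block drawn as two haplotypes per individual from the block
  frequencies (AGC 0.634, CAT 0.273, six rare haplotypes totalling
  0.093, matching the emulated genotype table), inducing Hardy-Weinberg
  proportions and tight LD; two independent SNPs drawn binomial(2, freq).
* Environment X: normal within sex, truncated to the instrument's
  theoretical [−3, 3] range. Women are shifted up by Cohen's d = 0.49.
  Because truncation at these parameters shrinks the SD by about 0.024
  and the sex mixture inflates it, the pre-truncation center and
  within-sex SD are moment-matched numerically so the generated bounded
  scores have exactly the configured marginal mean 0.57 and SD 0.98 —
  the observed moments of the emulated instrument.
* Outcome: the crossover-interaction model above, with Z = risk-haplotype
  carrier status. Regime presets place the crossover mid-range
  (differential susceptibility; the published haplotype/neuroticism
  coefficients b2 = 7.405, b3 = −12.651), exactly at the +2 SD edge
  (diathesis-stress) or the −2 SD edge (vantage sensitivity), or set
  b3 = 0 (null). The edges are "at" rather than "beyond" the range
  because a crossover beyond the edge leaves a significant group
  difference of the wrong sign at the near edge in large samples, which
  would contaminate the intended pattern.
* Residual SD is derived from a target adjusted R² (published tables
  report adjusted R², not residual variance): with X ⊥ Z,
  `var_lp = b1²Vx + qz b3²Vx + qz(1−qz)(b2 + b3·Ex)² + 2 b1 b3 qz Vx`
  and `σ² = var_lp (1 − R²)/R²`, where R² is backed out of the adjusted
  value at the configured n. Default target: 0.123.
* One RNG stream per component (genotypes, environment, noise), spawned
  from the master seed; identical configs give byte-identical output
  files.

What the generator does **not** emulate: item-level life-event responses
(only the summary score), population stratification, genotyping error,
any non-normality of the real environment score beyond truncation, and
sex effects on the outcomes (sex affects only X by default, with hooks
for covariate testing). Passing calibration tests on these synthetic
studies therefore demonstrates correctness of the estimators and decision
rules under the stated generative assumptions, not robustness to
violations of them.

## Numerical choices and problem sizes

* EM: tolerance 1e-8 on the log-likelihood, max 500 iterations, 10
  restarts; non-convergence returns the best estimate flagged.
* RoS roots are the closed-form quadratic roots; tests verify them
  against a 1e-4-step grid search to 1e-3.
* PoI closed form is verified against trapezoid integration of the
  between-line area to 1e-6.
* OLS is verified against a direct normal-equations solve to 1e-8.
* Calibration suites use 2,000 replicates at n = 86 for type-I error and
  parameter recovery, and 100 replicates per regime at n = 2,000 for
  end-to-end classification recovery — sizes at which Monte-Carlo noise
  is small relative to the tested margins while the whole suite remains
  quick on a single CPU. At n = 86 classification recovery degrades
  (interactions of the published magnitude are near the detection
  threshold); that behaviour is reported by example, not asserted.

## Known limitations

* The indices themselves have documented methodological limitations and
  newer alternatives exist; this package deliberately implements the
  classical definitions and does not attempt those refinements.
* Regions of significance on the moderator (Z) are not computed.
* The EM phasing assumes random union of haplotypes; it is adequate for
  a small tag-SNP block, not a general-purpose phaser.
* One published regression row (social anxiety, rs3800373) prints a
  crossover and PoI that are inconsistent with its own printed
  coefficients; the package computes the coefficient-implied values
  (0.846 and 0.36), which is why two acceptance cases fail by design.
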