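# Methods

## The model

The package analyses trial-level emotional ratings of evocative pictures
through the lens of the Evaluative Space Model (ESM): positivity and
negativity are treated as partially separable response systems whose
activation varies linearly with rated arousal,

```
positivity_ij = p0 + p1 * arousal_ij + (subject, stimulus effects) + e_ij
negativity_ij = n0 + n1 * arousal_ij + (subject, stimulus effects) + e_ij
```

Two derived quantities carry the theory:

* **positivity offset** = `p0 - n0`, the surplus of positive over negative
  activation in a low-arousing context (arousal = 0);
* **negativity bias** = `n1 - p1`, the steeper growth of negativity with
  arousal.

Both are estimated inside one multilevel model.  The two activation
functions are stacked into a single outcome, *emotional activation*:
positivity ratings on pleasant trials plus a random half of each
participant's neutral trials, and negativity ratings on unpleasant trials
plus the other half.  The neutral split is drawn per participant so that no
stimulus appears on both sides, which keeps a by-stimulus random intercept
well defined.  Fixed effects are the activation-function factor (negativity
as reference, so its coefficient *is* the offset), arousal on its raw 0–8
coding, and their interaction (whose negative is the bias).  A third and a
fourth model family use the same machinery with stimulus category as the
fixed factor: raw responses (positivity, negativity, arousal) and the
per-trial ambivalence index

```
ambivalence = (positivity + negativity)/2 - |positivity - negativity|
```

which ranges over [-4, 8] on 0–8 scales: the first term is the strength of
co-activation ("total affect"), the second the response's polarity.

Symptom moderation is cross-level: each of four scales (three CAPE
subscales scored as item means in [1, 4]; the 43-item CAS anhedonia sum)
is unit-rescaled by its possible maximum, centered to the sample mean, and
entered — one scale per model — with interactions against every level-1
term, alongside age, a male indicator, years of education, and the
respective other symptom domains as covariates.  Conditional (simple)
effects within factor levels are computed only when the omnibus interaction
reaches trend level (p < .10); interaction p values are Bonferroni-corrected
within the four-moderator family per response variable (both the trend gate
and the family are configurable).

## Estimation

All models are linear mixed models with by-subject random terms crossed
with by-stimulus random intercepts, estimated by profiled REML on the
sparse mixed-model equations (see the `lmm_engine` module docstring for the
algebra).  Design choices that were genuinely open:

* **Random-slope coding for the activation factor.**  The by-subject random
  slopes use effect coding (±1/2) rather than the treatment coding of the
  fixed part.  With heterogeneity placed symmetrically on the two functions,
  a single variance component then equals the between-subject variance of
  the offset itself (likewise for the bias), and the fitted SD is directly
  comparable to a reported between-subject SD.
* **Covariance structure.**  Variance components are independent
  ("diagonal") by default, except the by-subject (offset, bias) pair in the
  activation model, which gets an unstructured 2×2 covariance
  (Cholesky-parameterized, diagonal entries bounded at zero).  Rationale:
  when one symptom factor moderates both the offset and the bias — the
  situation the moderation analysis targets — a person's offset and bias
  deviations are necessarily correlated, and forcing independence
  underestimates the offset's standard error (observed as ~88% coverage of
  a nominal 95% CI in pilot recovery runs; near-nominal with the
  correlated block).  `correlated_slopes=False` restores the diagonal
  structure.
* **Optimization.**  L-BFGS-B on the relative Cholesky parameters with a
  two-stage start (variances first with correlations pinned at zero, then
  released, plus the unit start; the best optimum is kept) and a
  Nelder-Mead polish if line search reports failure.  The objective returns
  +inf at degenerate parameters.  Relative tolerance 1e-13 on the
  deviance; boundary variances are reported as exactly 0.
* **Degrees of freedom.**  Satterthwaite, computed from a numerical
  gradient of the contrast variance and a numerical Hessian of the REML
  deviance in (theta, sigma²) coordinates — the same construction lmerTest
  uses, against which the engine is tested (estimates, SEs, variance
  components and dfs agree to fractions of a percent on a shared dataset).
  Multi-column omnibus F tests combine per-eigencontrast dfs via
  `df2 = 2E/(E - r)`, `E = sum(nu_i/(nu_i - 2))`.  When every variance
  component sits on the boundary the df falls back to the residual rule
  `n - p`; in the no-random-effects limit the fit is exactly OLS with
  `df = n - p`.
* **Standardized effects.**  β = b·SD(x)/SD(y) with observation-level SDs
  computed on the analysis dataset; an alternative basis can be applied by
  the caller since raw b, SDs and CIs are always reported.

## The synthetic-data generator

The generator is the estimation model run forwards, at the study's scale:
261 participants × 48 stimuli (16 per category, half social), integer 0–8
ratings.  Arousal is drawn per trial from its category's normal
distribution (pleasant 3.80/2.40, neutral 2.87/1.93, unpleasant 5.02/2.40 —
the last chosen so the unpleasant-vs-pleasant arousal contrast is 1.22 in
expectation) and discretized first; congruent responses then follow the
activation functions of the *realized* integer arousal with defaults
p0 = 5.29, p1 = 0.01, n0 = 2.89, n1 = 0.42 (offset 2.40, bias 0.41).
Subject heterogeneity is a bivariate (offset, bias) deviation with total
SDs 0.92 and 0.17, split symmetrically onto the two functions; by-stimulus
intercept SD 0.3; residual rating noise SD 1.2 (chosen as a realistic
within-person noise level for 9-point affect scales).  Incongruent
responses (positivity toward unpleasant pictures, negativity toward
pleasant ones) are flat low-mean responses (1.5 / 1.0).

Symptom scores come from a latent 4-variate Gaussian with the study's
marginal means/SDs and CAPE inter-correlations in the reported 0.72–0.79
band, mapped to each scale's granularity (CAPE item-mean grid with 20/14/8
items; CAS integer sum) and clipped to the valid range.  Moderation is
generated through a single driving scale by default (CAPE negative
symptoms; per-SD slopes −0.66 on the offset and −0.13 on the bias, read off
the moderated-model grid), because the reported per-moderator coefficients
come from separate models over strongly correlated scales — applying all
four at once would reproduce none of them.  The other scales pick up
association through the latent correlation, which is also how such data
behave.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: a raw category contrast in congruent valence
(under the fitted activation functions, pleasant and neutral trials carry
nearly identical expected positivity, so the category analyses are
exercised with an explicit optional `pleasant_positivity_shift`); ordinal
response styles (the discretization is round-and-clip on a linear-Gaussian
response); picture-level content effects beyond an exchangeable intercept;
and any temporal structure across trials.

Discretization is the one systematic distortion the defaults do carry:
clipping at the 0/8 boundaries (≈4% of ratings at defaults; the fraction is
reported and warned about above a configurable ceiling of 10%) compresses
extreme responses and biases the recovered offset downward by roughly 0.05
at the default noise level.  Recovery runs quantify this rather than hide
it: across 100 simulate-and-refit replicates at 60 subjects × 24 stimuli
the mean estimated offset is ≈2.37 (true 2.40, RMSE ≈0.20) and the mean
bias ≈0.40 (true 0.41), with 95% CI coverage ≈0.91–0.93.

## Numerical and procedural details

* Problem sizes: the bundled analysis scripts run the full 261 × 48 study
  (a base + four moderated fits per family, ≈12,500 rows, ≈800 random
  effects, a few seconds per fit); tests and the recovery harness use
  reduced sizes (30–60 subjects, 24 stimuli) that preserve the crossed
  structure.
* All randomness (generation, neutral split, replicate streams) flows from
  explicit integer seeds through `numpy` seed sequences; identical
  configuration yields byte-identical outputs, and the neutral split is
  invariant to row order.
* Rating validation is strict: non-integer or out-of-range ratings and
  duplicate participant × stimulus pairs are rejected with the offending
  rows named, never coerced.  Questionnaire scoring rejects missing items
  rather than imputing (the instrument used forced entry).
* Screening: "more than 50 similar answers in a row" is implemented as a
  strict-inequality run of identical values over the concatenated
  questionnaire + task stream (runs may span the boundary; configurable),
  and task completion ≥ 75% is inclusive at the boundary.
* Cohen's d for the arousal-norm comparison pools SDs as their unweighted
  root mean square (group sizes for the normative data are not available);
  an n-weighted variant is provided.
* Aliased fixed-effect columns are dropped (first occurrence kept) with a
  warning; single-category inputs raise a degenerate-design error; zero
  neutral trials for any participant make the activation design
  unconstructible.

## Known limitations

* The Satterthwaite Hessian is numerical; on near-boundary fits the
  information matrix can be ill-conditioned, in which case dfs fall back to
  `n - p` (this inflates dfs but leaves estimates and SEs untouched).
* The engine fits Gaussian outcomes only; the 0–8 ratings are treated as
  conditionally normal, as in the analysis it reimplements.
* With very small stimulus sets (< ~8 per category) the offset is an
  extrapolation to arousal 0 through few stimulus clusters and becomes
  seed-sensitive; the recovery defaults use 24 stimuli for that reason.
* An unstructured covariance across *more* than one grouping factor (e.g.
  correlated subject and stimulus terms) is not expressible — nor needed
  for these designs.
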