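# Methods

## The instrument and its scoring

The questionnaire asks mothers of 24–72-month-old children about seven
screen-exposure characteristics over the last month. Each item is scored
on a small ordinal range and the scores are summed:

| Item | Raw response | Score |
|---|---|---|
| Daily screen time | hours/day, weekday and weekend, TV and other devices | <1 h → 0, 1–2 h → 1, >2 h → 2 |
| Co-viewing | always / sometimes / rarely ever | 0 / 1 / 2 |
| Screen limits | set & obeyed / not set / set but not obeyed | 0 / 1 / 2 |
| Use during meals | no / yes | 0 / 1 |
| Use in the hour before bedtime | no / yes | 0 / 1 |
| Age of first exposure | completed months | ≥24 → 0, 18–23 → 1, 12–17 → 2, <12 → 3 |
| Low-quality content | count of distinct inappropriate content kinds | 0 → 0, 1 → 1, ≥2 → 2 |

Average daily time is the weekly-weighted mean
[(TV_wd + other_wd)·5 + (TV_we + other_we)·2]/7. Subscales: *rules* =
time + co-viewing + limits (0–6), *routines* = meals + bedtime (0–2),
*conditions* = onset + content (0–5). The total is 0–13; enumeration of
all 1296 rubric combinations confirms every value in {0,…,13} is
attainable. A child is *high PSE* when the total reaches the cutoff
(default 7, the 85th-percentile nearest-rank order statistic of the
development sample; the comparison is inclusive).

Numerical conventions chosen here where the instrument's description is
silent:

- **Time-bin boundaries.** The middle bin is closed: exactly 1 h and
  exactly 2 h both score 1, so every duration maps to exactly one score.
- **Percentile method.** Nearest rank (value at rank ⌈p/100·n⌉), not a
  normal approximation: the score is discrete and right-skewed, so the
  empirical order statistic is the defensible definition.
- **Onset binning.** Completed months, edges as printed (24 months → 0).
- The onset item's 0–3 range (vs 0–2 elsewhere) is implemented as
  specified by the instrument; no reweighting is offered.

## Sample-size design

`required_sample_size` implements the infinite-population prevalence
formula n = ⌈DEFF · Z² p(1−p)/d²⌉ with Z the exact two-sided normal
quantile (1.6449 at 90%). No finite-population correction is applied;
with p = 0.5, 90% confidence, d = 0.05, DEFF = 1 the result is 271 per
centre.

## Psychometric battery

Implemented from the defining formulas on the n×7 item-score matrix,
with Pearson correlations on the ordinal scores (not polychoric) and
unbiased (n−1) variances throughout, so Cronbach's α is internally
consistent between its variance and covariance forms:

- **KMO** = Σr²ᵢⱼ / (Σr²ᵢⱼ + Σq²ᵢⱼ) over i≠j, with q the anti-image
  partial correlations −R⁻¹ᵢⱼ/√(R⁻¹ᵢᵢR⁻¹ⱼⱼ). An identity correlation
  matrix yields 0 with a warning (no shared variance).
- **Bartlett**: χ² = −(n−1−(2k+5)/6)·ln det R on k(k−1)/2 df.
- **PCA factors**: eigendecomposition of the correlation matrix
  (correlation, not covariance — the items have different ranges);
  retention by strict Kaiser rule (λ > 1) with an override for a fixed
  factor count; loadings vᵢ√λᵢ with each component's sign set so its
  largest loading is positive; items assigned to the factor with the
  largest absolute loading. No rotation is applied.
- **α** = (k/(k−1))(1 − Σσ²ᵢ/σ²_T). Negative values are permitted (and
  arise for adversarial inputs); exactly cancelling items (zero total
  variance) are a hard error.

The Kolmogorov–Smirnov normality check in `distribution_summary` is the
Lilliefors variant (parameters estimated from the sample), matching the
behaviour of the common statistical packages; skewness and excess
kurtosis use the bias-corrected sample estimators.

## Association analysis

- **χ²**: Pearson, no continuity correction by default (a flag restores
  Yates), matching the uncorrected large-sample convention the printed
  odds ratios are consistent with.
- **Crude OR**: cross-product (a·d)/(b·c) with Woolf log-method 95% CI.
  The Haldane–Anscombe +0.5 is added to all four cells only when a zero
  cell occurs, and the corrected cells are stored on the estimate.
- **Count reconstruction**: cells are rebuilt from printed (N, %) pairs
  as ⌊N·pct/100 + 0.5⌋ (ties half-up). Reconstruction reproduces 25 of
  the 26 published crude ORs to 2 decimals; the single mismatch
  (maternal occupation, 2.16 vs 2.17) traces to the rounding of the
  printed percentages, so only consistently reconstructing rows serve as
  exact validation targets.
- **Subgroup letters**: pairwise uncorrected 2×2 χ² at α = 0.05; levels
  are processed in table order and existing letters are tried
  newest-first, so a level joins the most recently formed compatible
  group. This tie-break reproduces the published a/b/b/c daycare pattern
  on reconstructed counts; oldest-first assignment would instead attach
  the small childminder group (n = 58, underpowered against every other
  level) to the first group. A degenerate pairwise table (zero expected
  cell) counts as no evidence of difference.
- **Adjusted model**: logistic regression of high PSE on dummy-coded
  covariates (18 covariates, 27 parameters; anthropometric z-score bands
  enter the crude table only, including an explicit "missing" level, and
  are excluded from the model). The fit is Newton/IRLS (statsmodels) to
  tolerance 1e-8, max 100 iterations; Wald CIs; an events-per-parameter
  warning below 10; a pre-fit screen raises a named error when the
  outcome is constant within a dummy level (complete or quasi-complete
  separation).

## Synthetic cohort generator

The development study's raw data are not deposited, so the pipeline is
exercised on synthetic cohorts built to the structure the analysis
assumes:

1. **Covariates** are drawn independently from the published marginal
   distributions (only marginals are published; any joint distribution
   matching them is an assumption). Child age is uniform within the
   drawn age band; the three anthropometric z-scores are standard normal
   — z-scores are standardised by construction — independent of the
   outcome (the study found no association), and jointly missing for a
   configurable share of children (default 0.226).
2. **Class assignment**: P(high) = expit(β₀ + Σ log OR) using the
   published crude odds ratios as level effects; β₀ is solved by Brent's
   method on a 200 000-draw Monte-Carlo average of the expit so the
   expected prevalence is 0.225. Because the crude ORs are treated as
   marginal effects of a joint logistic model, the crude ORs realised in
   simulation are mildly attenuated toward 1 (non-collapsibility); they
   remain inside the published confidence intervals, which is the
   calibration the tests assert.
3. **Item responses**: given the class, the seven item scores are drawn
   from class-conditional categorical distributions coupled by a
   Gaussian copula (correlation ρ = 0.36 on the latent scale, shared
   within each subscale block), then rejected and redrawn until the
   total lands on the intended side of the cutoff (≥7 for high). Raw
   responses are then synthesised from the scores — screen hours are
   drawn inside the scored time bin with weekday/weekend variation and a
   random TV share, onset months inside the scored age bin (never
   exceeding the child's age), content kinds at or above the scored
   count — so scoring is exercised end to end and every generated record
   passes validation. Hour draws avoid the exact bin edges so floating
   rounding cannot flip a score.

The class-conditional probabilities and ρ were calibrated once by
simulation against the published score distribution and then frozen as
the package defaults. The resulting default cohort has median total 4,
IQR 3–6, subscale medians 2/0/2, an 85th-percentile cutoff of 7, three
retained components grouping the items exactly into the subscales,
α ≈ 0.44 and KMO ≈ 0.64 (published: α 0.49, KMO 0.61 — these depend on
the unavailable raw data and serve as vicinity anchors, not exact
targets). The rules-subscale IQR realises as 1–3 versus the published
1–4; the medians, which are the calibrated quantities, match.

**Determinism.** A cohort is a pure function of (configuration, seed):
one numpy `default_rng(seed)` stream is consumed in a fixed order, and
repeated generation is bit-identical (tested). Records are *not*
invariant to changes of n, because the rejection-sampling step consumes
a data-dependent amount of randomness; per-record counter-derived
substreams were considered and rejected as disproportionate to the
benefit.

**What the generator does not emulate.** Covariate dependence (e.g.
kindergarten attendance increasing with age), item-level association
with covariates beyond the low/high class, reporting error, and
missingness outside the anthropometric block. Passing calibration tests
therefore shows the pipeline recovers the published structure under the
assumed data-generating process, not that the instrument behaves this
way in new field data.

## Problem sizes used in checks

Calibration checks use 20 cohorts of n = 1245 (the study's size);
parameter recovery uses 200 cohorts of n = 5000 for the configured
OR = 2.0 check (recovered within 10%) and 40 cohorts of n = 2500 for
null coverage; marginal-convergence checks use a single n = 10 000
cohort. These sizes keep every Monte-Carlo standard error well below
the tolerance it is compared against.

## Known limitations

- The generator's independence assumptions make adjusted and crude
  estimands nearly coincide; confounding structure cannot be studied
  with the default configuration (effects can be reconfigured freely).
- The open-ended content item must arrive pre-coded as a count of
  inappropriate content kinds; no text coding is attempted.
- All seven items are required; partially answered questionnaires are
  rejected rather than imputed.
- Exact boundary durations (average of exactly 1 h or 2 h) follow this
  package's closed-middle-bin rule; instruments transcribed from paper
  forms may have resolved ties differently.
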