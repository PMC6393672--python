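# Methods

## Scope and model

`racebench` analyses simple-RT experiments in the redundant signals
paradigm: interleaved auditory (A), visual (V), redundant (AV) and
catch trials, with responses valid inside a 1.5-s window. The analysis
has three stages — quantile-area benefits against Raab's
probability-summation prediction, measurement of history effects and
Miller's-bound violations, and maximum-likelihood fitting of a
context-variant race model — plus a generator that simulates
experiments with exactly the structure the model assumes.

The modelling core works in rate space, `r = 1/RT`. Each unisensory
channel is a LATER unit: `r ~ N(μ, σ²)`. A redundant trial is decided
by the unit whose rate is higher, so the redundant rate is
`max(R_A, R_V)` with `(R_A, R_V)` bivariate normal. Two parameters
extend the basic race:

- `ρ ∈ (−1, 1)`: rate correlation across the two units. History
  effects (repetition priming of the previous trial's modality) induce
  a negative correlation between the channels' momentary
  effectiveness.
- `η ≥ 0` (1/s): additional accumulation noise present only in the
  redundant condition, applied additively to both standard deviations,
  `σ'_k = σ_k + η`. This is the context-invariance violation: with
  `η > 0` the redundant CDF may exceed `min(P_A + P_V, 1)`.

The density of the maximum is closed-form,
`f(z) = φ_1(z)·Φ(h_2(z)) + φ_2(z)·Φ(h_1(z))` with
`h_k(z) = (z_k − ρ z_j) / √(1−ρ²)` in standardised coordinates; the
CDF is the bivariate normal CDF at `(z, z)`. The likelihood ignores the
(unnormalised) mass at `r ≤ 0`: at typical parameter scales
(μ ≈ 2.4–3.3/s, σ' ≲ 0.7/s) that mass is at most ~1e-5; the fitted
model records it (`neg_rate_mass_`) and warns above 1e-4, where
truncation could start to influence the likelihood.

## Numerical choices

- **Bivariate normal CDF.** Computed via the tetrachoric integral
  `Φ₂(a,b,ρ) = Φ(a)Φ(b) + ∫₀^ρ φ₂(a,b;r) dr` with fixed 128-node
  Gauss–Legendre quadrature. This is deterministic and accurate to
  ~1e-12 for |ρ| ≤ 0.99 (cross-checked against an independent library
  implementation in the tests); `ρ = ±1` uses the exact comonotone /
  antithetic limits.
- **Quantile convention.** Everywhere the sorted sample point `x_(j)`
  sits at probability `(j − 0.5)/n` and quantiles are read on the grid
  `p_i = (i − 0.5)/N` with `N = 50`. This symmetric convention is
  applied identically to the empirical, predicted, bound and model
  CDFs, which is what the area estimators require. Outside the sample
  extremes the CDF is clamped to 0/1; no tail mass is invented.
- **Combined CDFs (Raab, Miller).** The unisensory piecewise-linear
  CDFs are evaluated on a dense 2,001-point grid spanning the union of
  the supports, combined pointwise, and inverted by linear
  interpolation with a smallest-t tie rule on flat segments. The grid
  keeps inversion error well below 1 ms at usual RT ranges; because
  both the prediction and the bound are inverted from the same grid,
  their ordering (`Miller_i ≤ Raab_i`) is preserved exactly.
- **MLE.** `(ρ, η)` are estimated by bounded L-BFGS-B from a 3 × 3
  multi-start grid (ρ within [−0.99, 0.99], η within [0, 2/s]),
  keeping the best optimum; the returned log-likelihood always
  dominates every starting point. Convergence tolerance 1e-8; the fit
  records a `converged_` flag.
- **Model RT quantiles.** The race RT CDF `1 − Φ₂(1/t, 1/t)` is
  inverted by vectorised bisection on t ∈ [0.05, 1.5] s (bracket
  widened automatically if needed) to 1e-6 s.
- **Outlier rule.** Per participant × condition × modality cell, rates
  beyond `3 × 1.4826 × MAD` from the cell median are excluded —
  equivalent to 3 SDs under normality (expected exclusion 0.27 %). A
  zero-MAD cell retains all points with a warning: excluding anything
  on zero spread would be arbitrary. Even-length medians are the mean
  of the two central order statistics.
- **History labels.** Only a preceding unisensory trial classifies the
  current unisensory trial (repetition/switch); trials preceded by AV
  or catch trials, and the first trial of each block, are excluded.
  The per-modality effects are averaged unweighted. Alternative
  conventions (e.g. counting AV as a repetition of both) can be built
  on the `previous_modality` column the labeller also emits.

## Synthetic experiments

`SimConfig` defaults describe a fast audio-visual detection cell:
μ_A = 3.3/s, μ_V = 3.2/s (median RTs near 0.30 s), σ = 0.4/s,
ρ = −0.18, η = 0.16/s, 104 trials per modality in blocks of ~104 trials
at 25 % catch rate. These are the scales at which the estimators and
the acceptance checks are exercised; the cohort used by
`scripts/acceptance.py` adds a slower "complex" construction level
(μ ≈ 2.4/s) with weaker redundant noise (η = 0.09/s vs 0.22/s) and a
34 ms switch cost, reproducing the qualitative dissociation between
benefits (larger for slow/variable channels, by the variability rule)
and bound violations (larger where η is larger).

History effects are injected as an additive RT shift on unisensory
trials whose immediate predecessor carried the other unisensory
modality; the redundant race itself is history-free. This is a test
harness for the Step-2 estimator, not a mechanistic claim: in real
data history acts on the decision process itself, which is exactly why
the race model represents it as a rate correlation rather than an RT
shift. Consequently the pipeline's fitted `ρ` on switch-cost data is
*more* negative than the generative `ρ` — the parameter absorbs the
injected history structure — while `η` recovery is unaffected.

Draws producing non-positive rates or RTs beyond the response window
are resampled rather than truncation-corrected; at the default scales
the affected mass is ≤ 1e-4 and no estimator is measurably biased by
it. The generator does not simulate foreperiods, dummy trials,
feedback, false alarms or misses; catch trials are always correctly
withheld. Passing tests on synthetic data therefore demonstrate
estimator correctness under the model's own assumptions — they do not
certify robustness to contaminants real data may contain (anticipatory
responses, lapses, non-Gaussian rate tails).

## Statistical conventions and limitations

- Group summaries are grand means over each participant's condition
  cells with SEM across participants. Inferential statistics (ANOVA,
  t-tests) are deliberately out of scope; the tidy CSVs are the
  interface to external stats environments.
- Whether `η` should inflate the SD or the variance is a genuine
  modelling choice; this package adds it to the SD. With ~100
  redundant trials per cell the two variants are not empirically
  distinguishable, but fitted `η` values are only comparable between
  implementations using the same convention.
- Single-cell `(ρ, η)` estimates at ~100 trials are noisy and `ρ` in
  particular is weakly identified (the likelihood surface is shallow
  in `ρ` when `η` is free); cohort means are the interpretable
  quantity. Recovery is unbiased at the 2-SE level across 50 synthetic
  participants (verified in the acceptance tests).
- The 50-point quantile grid and the (i − 0.5)/N convention introduce
  small estimator-specific offsets relative to other quantile
  conventions; published area values computed with different
  conventions can differ by a few ms.
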