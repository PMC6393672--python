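# racebench

Race-model analysis of the **redundant signals effect** (RSE): the
speed-up of simple reaction times when two signals (for example an
auditory and a visual one) are presented together rather than alone.

The package implements a three-step comparative analysis of trial-level
RT data, together with a synthetic-experiment generator that shares the
same generative structure, so every stage can be validated by parameter
recovery without access to laboratory data.

**Step 1 — benefits.** The multisensory benefit is the area between the
redundant-condition CDF and the faster of the unisensory CDFs,
estimated on matched quantile grids (N = 50 points, `p_i = (i-0.5)/N`):

    benefit = Σ_i [ min(A_i, V_i) − AV_i ] / N

Raab's race model predicts the redundant CDF parameter-free from the
unisensory CDFs by probability summation,
`P_AV(t) = P_A(t) + P_V(t) − P_A(t)·P_V(t)`, giving a predicted benefit
on the same scale.

**Step 2 — interactions.** Two effects fall outside Raab's model.
History effects: unisensory responses are slower after a modality
switch than after a repetition
(`history effect = mean RT_switch − mean RT_repetition`, per modality,
averaged). Violations of Miller's bound: under any context-invariant
race the redundant CDF cannot exceed `min(P_A + P_V, 1)`; the violation
area `Σ_i max(Miller_i − AV_i, 0) / N` measures how far real data break
that bound.

**Step 3 — the context-variant race model.** Modelling happens in rate
space (`r = 1/RT`). Each unisensory condition is fit by a LATER unit —
a Gaussian rate distribution with mean `μ` and SD `σ`. The redundant
condition is modelled as the maximum of the two units' rates, a
correlated bivariate normal with two free parameters estimated by
maximum likelihood:

- `ρ` — the correlation between the units' rates, absorbing history
  effects (typically negative: a visual trial speeds the next visual
  response but slows the next auditory one);
- `η` — additional accumulation noise in the redundant condition, added
  to both σs (`σ'_k = σ_k + η`). A positive `η` breaks context
  invariance and is what permits violations of Miller's bound.

Preprocessing follows robust conventions: responses are valid within
1.5 s of signal onset, and outliers are removed per condition in rate
space using a `3 × 1.4826 × MAD` criterion (the 3-SD analogue under
normality).

## Worked example

```python
import racebench as rb

# one participant, one condition: correlated race with added noise
# and a 30 ms modality-switch cost
config = rb.SimConfig(rho=-0.18, eta=0.16, switch_cost=0.03, seed=7)
trials = rb.simulate_experiment(config)

report = rb.run_pipeline(trials)
row = report.cells.iloc[0]
for stat in ("empirical_benefit_s", "predicted_benefit_s", "model_benefit_s",
             "history_effect_s", "violation_area_s", "rho", "eta"):
    print(f"{stat:22s} {row[stat]: .4f}")
```

prints

```
empirical_benefit_s     0.0332
predicted_benefit_s     0.0202
model_benefit_s         0.0333
history_effect_s        0.0399
violation_area_s        0.0084
rho                    -0.5061
eta                     0.1652
```

Reading the numbers: redundant responses were on average 33 ms faster
than the faster unisensory channel (the empirical benefit). Raab's
independent race predicts only 20 ms — the data show real interactions:
a ~40 ms switch cost (close to the 30 ms injected plus sampling noise)
and an 8 ms violation of Miller's bound. The fitted race model absorbs
both: `η ≈ 0.17/s` recovers the generative noise (0.16/s), and the
strongly negative `ρ` soaks up the history structure that the additive
switch cost induced, letting the model benefit (33 ms) match the
empirical one. At ~100 redundant trials per cell, single-cell `ρ`
estimates are noisy; group means across participants are the
interpretable quantity.

The same analysis runs from the shell:

```sh
racebench simulate --out trials.csv --participants 5 --seed 1
racebench analyze --trials trials.csv --out results/
racebench demo            # simulate + analyze in one go
```

`results/` then contains per-cell statistics (`cells.csv`), outlier and
performance tables, and a plain-text group summary.

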