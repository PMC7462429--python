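# thoughtnet

Analysis pipeline linking resting-state functional connectomes,
experience-sampling reports of ongoing thought, and self-reported
well-being — with a synthetic cohort generator that plants known structure
so every inferential stage can be validated end to end.

## Who this is for

Researchers in network neuroscience who relate individual differences in
functional connectivity to behavioural or experiential covariates, and who
want a tested, scriptable implementation of the full chain:

1. **Thought-pattern decomposition** — items of a Likert (1–4)
   experience-sampling questionnaire are Ward-clustered into two groups;
   each group is reduced by PCA on the item correlation matrix with
   varimax rotation (Kaiser normalization), yielding six per-subject
   component scores via the regression method. Fitted models can be
   *imposed* on a second session without refitting.
2. **Network-based statistic (NBS)** — for each score, an edgewise GLM on
   fully connected signed connectomes (nuisance: intercept, mean
   connectivity, age, gender, motion fraction) is thresholded at
   `|t| ≥ T` (default `T = 3.2`); connected suprathreshold components are
   assigned family-wise-error-corrected p-values from a permutation null
   of the maximal component size (default 5,000 permutations,
   `p = (k + 1)/(n_perm + 1)`, α = 0.05).
3. **Signed graph metrics** — on connectomes masked to a significant
   component: positive/negative/total node strength,
   *fractional strength* `F = S⁺ / S⁻` (the ratio of summed positive to
   summed negative weight, analyzed as `ln F`), and weighted betweenness
   centrality on edge lengths `1/|w|`.
4. **Test-retest reliability** — ICC(2,1) with percentile-bootstrap CIs
   and an F-test, plus Pearson correlation of session-to-session changes
   (score change vs. change in `ln F`), separating trait-like from
   state-like patterns.
5. **Mediation** — percentile-bootstrap (default 5,000 resamples)
   mediation of brain (`ln F`) → thought score → well-being domain with
   covariates, standardized paths `a`, `b`, `c`, `c′`, indirect effect
   `a·b`, and the exact decomposition `c = c′ + a·b`.

The statistical model of the NBS stage is, per edge *(i, j)*:

```
w_ij = β₀ + β₁·score + γ'·[mean_conn, age, gender, motion] + ε,
t_ij = β̂₁ / SE(β̂₁)
```

with component "size" = edge count and the null distribution built by
jointly re-shuffling the interest block across subjects.

## Worked example

```bash
python examples/04_reliability_and_mediation.py
```

prints (seed 11, 200 subjects, 60 nodes, 40-subject retest arm):

```
state-like thought factor: ICC = 0.23 [-0.06, 0.47], p = 0.0750
trait-like thought factor: ICC = 0.51 [0.26, 0.68], p = 0.0003
brain (log fractional strength): ICC = 0.71 [0.51, 0.82]
change-change coupling: r = 0.35, p = 0.0285
mediation brain -> thought -> psychological well-being:
  a = 0.50, b = 0.40, c' = 0.17
  indirect a*b = 0.20, SE = 0.05, 95% CI [0.116, 0.295] -> significant
```

The state-like pattern is unreliable across sessions yet its session-to-
session change tracks the change in its neural component, and it carries a
significant indirect (mediated) effect on well-being; the trait-like
pattern is reliable but shows no mediation — the qualitative dissociation
the pipeline is designed to expose. `examples/01–03` walk through the
decomposition, NBS discovery (planted 10-edge component recovered with
edge Jaccard 0.91 at FWE p = 0.001), and the graph metrics.

A thin CLI mirrors the library (`thoughtnet simulate | decompose | nbs |
metrics | reliability | mediate | run-all`); `thoughtnet run-all
--synthetic --out run/` chains every stage and writes a JSON run report
with a full config/seed echo.

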