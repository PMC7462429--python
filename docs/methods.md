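# Methods

This note documents the models, defaults, and design choices behind
`thoughtnet`, and what the synthetic generator does and does not emulate.

## Thought-pattern decomposition

Items (participants × items, Likert 1–4, no missing cells) are clustered
with Ward linkage on their response profiles (items as observations,
subjects as features) and the tree is cut into exactly two clusters. We
use scipy's Ward implementation, which reports merge heights on the
Euclidean scale; the Ward objective minimizes within-cluster squared
Euclidean error, so the partition is identical to a squared-distance
formulation and heights remain monotone.

Within each cluster, items are standardized and PCA is run on the item
*correlation* matrix (Likert items differ in variance). The retained
loadings (`fixed:3` by default; a strict Kaiser `eigenvalue > 1` rule is
available) are varimax-rotated with Kaiser row normalization (tolerance
1e−8, ≤ 1000 sweeps). Rotation is orthogonal, so item communalities are
conserved; sign indeterminacy is removed by making each component's
largest-magnitude loading positive, and components are ordered by rotated
explained sum of squares. Scores use the regression method,
`W = R⁻¹L`; a fitted model can be imposed on new sessions (session-1
means, sds, and weights — never refit), which is what makes
session-to-session change interpretable.

Components are named `clusterA_pc1 … clusterB_pc3`; the code never
depends on semantic labels.

## Connectomes

A connectome is the matrix of pairwise Pearson correlations between ROI
time series: symmetric, zero diagonal, fully connected (no thresholding,
no binarization), with signed weights kept because the positive/negative
balance is analyzed downstream. Raw r values are used (no Fisher z; a
`fisher_z` flag exists for sensitivity runs), no global signal regression,
no smoothing — preprocessing is upstream of this package. Edges are
indexed by the strict upper triangle, 0-based `(i, j)` with `i < j`.

## Network-based statistic

Per edge, OLS of weight on six thought scores (interest block) plus
intercept, mean connectivity (signed mean over the upper triangle), age,
gender, and motion fraction. The t-statistic of one contrast column is
thresholded at `|t| ≥ T` (two-sided by default so a single component can
carry both positive and negative associations; one-sided modes exist) and
connected components of surviving edges are extracted. Component size is
the *edge count* (extent); an intensity variant is not implemented.

The null distribution of the maximal component size is built by jointly
permuting the rows of the interest block (all six scores together, which
preserves their inter-correlation and the nuisance–connectome pairing);
Freedman–Lane residual permutation is available via `scheme=`. The
FWE-corrected p-value is `(k + 1)/(n_perm + 1)` where `k` counts null
maxima at least as large as the observed component; the unsmoothed `k/n`
is available (`smoothing=False`), and exhaustive enumeration of the
permutation group (small n) reports the exact `k/n_total`. Each of the
six contrasts is tested at α = 0.05 with no cross-contrast correction — a
faithful-but-liberal convention, noted here deliberately. Degenerate
zero-residual edge fits return a capped `|t| = 1e6` with a log note.

## Signed graph metrics

On a connectome masked to a component: positive strength
`Σ max(w, 0)`, negative strength `Σ |min(w, 0)|` (a **magnitude**, so
total = positive + negative), and fractional strength
`F = S⁺/S⁻` at node or graph level, reported with its natural log.
`F` is undefined when a graph (or node) has no negative or no positive
incident weight; undefined values propagate as missing — never zero — and
subjects with undefined `ln F` are dropped (with a logged count) from
downstream regressions. Betweenness centrality uses edge lengths
`1/|w|` on absolute weights (signed shortest-path semantics are
ill-defined, so this choice is deliberate and worth knowing about),
normalized so the middle of a 3-node path scores 1; components with fewer
than 3 nodes score zero. Group-level characterization averages
per-subject metrics, not metrics of the average graph.

## Reliability

ICC form is ICC(2,1) — two-way random effects, absolute agreement, single
measure — with ICC(3,1) behind a flag; the bootstrap CI is percentile over
subjects (default 5,000 resamples) and the p-value is the one-sided F-test
`MSR/MSE` with df `(n−1, n−1)`. Zero between-subject variance yields ICC 0
with a warning. Brain-side reliability is computed on `ln F` of the masked
component. Change coupling is the Pearson correlation of paired
session-2 − session-1 differences.

## Mediation

All paths are OLS on standardized variables (binary covariates left as
indicators), on the same complete-case sample, so `c = c′ + a·b` holds to
machine precision and is asserted in tests. Covariates are age, gender,
and motion fraction in every path model; mean connectivity is an
NBS-stage nuisance only. The indirect effect `a·b` is tested by
percentile bootstrap over subjects (resampling the standardized rows);
significance is the 95% CI excluding zero. Regression p-values for the
brain → well-being links are Bonferroni-corrected across the two
well-being domains (`min(1, 2p)`).

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 211 subjects (desk scale: 200), 264 nodes in 13
networks (desk: 60 nodes), 25 items, a 40-subject retest arm,
`noise_sd = 0.2`.

**Ratings.** Six latent factors (three per item cluster; within-cluster
factor correlation 0.25, zero across clusters — the within-cluster
correlation is what lets Ward separate the two item groups) load items at
0.95 with residual sd `sqrt(1 − 0.95²)·(noise_sd/0.2)`; latent items are
discretized at fixed quartile cutpoints into 1–4. These values were fixed
once so that the planted structure is recoverable through the Likert
bottleneck (recovered scores correlate ≈ 0.9 with the factors at n = 200);
item-specific endorsement rates and acquiescence styles are *not*
emulated.

**Connectomes.** A shared population matrix (random factor structure
`GGᵀ`, clipped) plus a subject-level offset (sd 0.05, which makes the
mean-connectivity nuisance non-degenerate and induces realistic
between-edge correlation), per-edge Gaussian noise
(sd `0.3·noise_sd = 0.06`), and the planted component shifts
`score × effect_per_edge × sign` on each planted edge, clipped to [−1, 1]
(saturation above 5% of planted edge values is warned about). Planted
components default to two disjoint connected 10-edge sets with base
weights ±0.25 in a 6/4 positive/negative split.

**Mediation calibration.** The configured `a_path` is realized through
the planted edge effect: linearizing `ln F = ln P − ln N` around the base
weights gives the factor sensitivity `g·β`, offset variance `(g·σ_δ)²`,
and noise variance `q·σ_e²`, from which the per-edge coupling `β` solving
`corr(ln F, factor) = a_path` follows in closed form. Monte-Carlo checks
show the realized correlation within ~0.01 of the target. Well-being is
then `c′·z(ln F) + b·factor + covariate effects + noise` on a
standardized scale, mapped to WHOQOL-like units (60 + 10·y). The trait
component instead carries a direct (unmediated) effect of 0.3 on the
social domain, producing the state/trait mediation dissociation.

**Retest.** Factor k evolves as `f₂ = ρ_k f₁ + sqrt(1−ρ_k²)·e` with
`ρ_k` = `trait_icc` (0.7), `state_icc` (0.15), or 0.4 for the remaining
factors — this makes the population ICC(2,1) of each factor equal ρ_k.
Session-2 connectomes reuse the base matrix and subject offset (the
persistent part of the brain measure) with fresh edge noise. Because
`a_path` and `state_icc` together *over*-determine the change-change
correlation, the session-2 driver of the state component is a mixture
`μ·f₂ + sqrt(1−μ²)·ξ` with `μ` solved (brentq on a closed form) to hit
`change_coupling` (0.4); if the target exceeds the attainable maximum the
generator uses μ = 1 and logs a warning. The trait component's change
coupling is not independently controlled and is nonzero at the defaults —
a known limitation relative to a fully trait-like pattern.

**What passing tests show.** The generator has Gaussian noise, linear
effects, a single site, no motion–connectivity coupling, no scanner
drift, and factor-pure items; recovery and error-control results
therefore validate the *inference machinery*, not robustness to the many
non-idealities of real fMRI/questionnaire data.

## Numerical choices and problem sizes

Simulations in the test suite use desk-scale conditions chosen as
realistic for the design: 200 subjects × 60 nodes (1,770 edges) for
recovery and the end-to-end run (1,000 permutations, 2,000 bootstrap
samples), 100 subjects × 40 nodes × 200 permutations × 200 replicate
cohorts for the family-wise error calibration, n = 500 for mediation
recovery and coverage (1,000 bootstrap samples, 300 replicates). Default
reporting settings remain 5,000 permutations and 5,000 bootstrap samples.
Seeds flow from single named `SeedSequence` roots per stage; identical
config + seed reproduces bit-identical cohorts and reports.
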