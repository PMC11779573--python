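# Methods

This note documents the models, estimators, numerical choices and known
limitations of `countergrad`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## The experimental design being modelled

The unit of analysis is a replicate cell of a factorial thermal-survival
assay: species (3 *Littorina* species) × population (northern or southern of
a biogeographic break) × treatment (ambient control, extreme heat, extreme
cold) × block (two sea-table batches), with 10 snails per cell — 180 snails
per block. Each snail is exposed for 3 h, scored for survival 21 h later,
and survivors are exposed and scored once more; the 48-h endpoint (alive
after both cycles) is the default phenotype, with the 24-h checkpoint
retained as an option because the modelled endpoint is a design choice, not
a property of the data format. Snails heavier than 1 g are excluded before
analysis (body size confounds thermal tolerance); the threshold is strict
(`> 1 g` removed, exactly 1 g retained).

## Synthetic data generator

`countergrad.synth` draws survival from a logit-linear model of the
*per-cycle* survival probability: `p = expit(beta0 + sum of matching
effects)`, with effects declared as `factor=level[:factor=level...]`
strings. The 48-h outcome composes two conditional Bernoulli draws with the
same `p` — the assay re-exposes survivors to the same treatment, and no
cycle-specific effect is assumed — so the expected 48-h cell survival is
`p^2` (a single-cycle mode exists). Note one consequence used by the tests:
a main-effects-only model on the per-cycle logit scale induces genuine
(small) interactions on the 48-h logit scale, because `logit(expit(eta)^2)`
is not affine in `eta`.

Extra-binomial noise, when requested, is a replicate-level beta perturbation
of `p` with intra-class correlation `rho`, giving count variance
`n p (1-p) (1 + (n-1) rho)` — the quasibinomial analysis downstream assumes
extra-binomial variance of unspecified mechanism, so one concrete mechanism
is chosen and checked by moment tests. Wet weights are log-normal
(mean 0.35 g, SD 0.12 g, clipped at 1 g) so the weight filter is a no-op
under defaults.

Preset scenarios fix the study conditions the analyses are exercised under:

- `countergradient` — control per-cycle logit 4.0 (≈ 96% 48-h control
  survival, the observed near-100% baseline), heat −3.0, cold −4.0 (cold
  harsher), a +1.5 northern advantage in both extremes, small
  species×treatment and treatment×block effects. The Cov_GE of the
  generating cell means is negative for every species (−0.68 to −0.95).
- `cogradient` — the mirror image (southern advantage).
- `null` — one shared survival probability (per-cycle logit 0.85 ≈ 0.49 at
  48 h), so phenotypes are exchangeable across groups: the correct null for
  permutation type-I checks and for the null contrast battery.
- `separation` — a treatment with survival probability numerically 1, to
  exercise bias-reduced fitting under complete separation.

## Bias-reduced quasibinomial GLM

Estimation maximizes the Jeffreys-penalized binomial log-likelihood
`l*(b) = l(b) + 0.5 log det X'WX`, whose gradient has the closed form
`X'(y - n*pi + h(0.5 - pi))` with `h` the leverages of the weighted
projection. This is Firth's mean-bias-reduced adjusted-score estimator for
the binomial-logit family, chosen as a clean objective that an independent
grid search can maximize (the tests do exactly that for 1–2 parameter
models, agreement ≤ 1e-3). Fisher scoring with step-halving; convergence at
score max-norm < 1e-8, cap 100 iterations; starting values from least
squares on the adjusted working response `logit((y+0.5)/(n+1))`. In
saturated designs the penalized fit equals the half-count
(Haldane–Anscombe) correction, e.g. the separated 2×2 slope
`log((10.5/0.5)/(5.5/5.5)) = log 21`.

Dispersion is `phi = Pearson X^2 / (N - p)` on survivor counts; the
coefficient covariance is `phi * (X'WX)^{-1}` and Wald inference uses a t
reference with residual df (standard quasibinomial practice; z is available
through the covariance directly). A saturated model has no dispersion
estimate and raises. AIC is `-2 l_binomial + 2p` **at the bias-reduced
estimates**: a quasi-likelihood has no AIC, so the binomial log-likelihood
is used, mirroring what the standard bias-reduction software reports.

Model selection removes interactions backward in stages (4-way, then 3-way,
then 2-way), greedily dropping one term per step when removal lowers AIC,
preserving marginality, never touching main effects, and recording every
candidate AIC in a trace. Because AIC retains a spurious k-df term whenever
its likelihood-ratio statistic exceeds 2k (probability ≈ 0.09–0.16,
independent of n), full pruning of a null interaction set is *not* expected
on every run; what the procedure reliably delivers — and what the tests
assert — is retention of generating interactions at realistic effect sizes
and removal of the highest-order terms.

Reference levels are alphabetical (littorea / N / control / A); contrasts
and AIC are invariant to this coding.

## Contrast battery

Marginal cell logits for the 18 species×population×treatment cells average
the block dimension with equal weights (the design is balanced), with
covariance propagated linearly from the phi-scaled coefficient covariance.
The battery has 21 rows — per treatment: 3 species pairwise differences
(populations averaged), 3 within-species N−S differences, 1 overall N−S
difference. Contrasts are computed on **survival** logits: positive N−S
means the northern group survived better. Benjamini–Hochberg is step-up
with the denominator `m` defaulting to the number of supplied p-values (21)
and overridable to 18, reflecting an ambiguity in the source analysis
between the table's row count and its stated test count; both options are
exposed, neither asserted as the original intent.

## Cov_GE

The chain restricts to the two extreme environments (control represents
neither home climate), pools blocks within genotype×environment groups (the
grouping is defined by genotype and environment only), and uses
replicate-level survival proportions as phenotypes:

1. standardize: subtract the grand mean of the phenotypes, divide by the SD
   of the group means;
2. marginal means: genotype means across environments and environment means
   across genotypes, equal-weight (the estimated marginal means of a
   two-factor ANOVA with interaction; identical to simple averages in the
   balanced design — unbalanced margins raise rather than guess a policy);
3. covariance over native pairs (N↔cold, S↔heat, configurable):
   `sum(G_i * E_pair(i)) / (n_pairs - 1)` (divisor 1 for two populations),
   clipped to [−1, 1].

The SD divisor uses the population (divide-by-k) convention, calibrated so
the perfectly additive anti-symmetric 2×2 case attains exactly −1 — the
natural calibration when the statistic's CI is reported against a −1 bound.
The sample (k−1) convention is available behind `sd_convention="sample"`;
its additive bound is ±0.75.

**Bootstrap.** Individuals are resampled with replacement within each
genotype×environment group (the binomial observation unit), re-forming
replicates of the original sizes — implemented exactly as binomial draws at
the group's pooled survival rate — and the full chain is recomputed per
resample; 999 runs, percentile 95% CI. Degenerate resamples (all group
means equal) are redrawn and counted. Replicate-level resampling is
available (`unit="replicate"`). With ~50 snails per group, binomial noise
inflates the SD-of-group-means denominator slightly, attenuating the
estimate toward zero; measured coverage of the percentile CI at an interior
truth of −0.75 is ≈ 0.93–0.95.

**Permutation.** Replicate phenotypes are shuffled across groups within
species; the full chain, including re-standardization, is recomputed;
two-sided add-one p. Because re-standardization makes Cov_GE scale-free,
its permutation null is the distribution of the statistic over random 2×2
cell-mean patterns and does **not** concentrate as measurement precision
grows: even a near-perfect additive pattern bottoms out around p ≈ 0.07–0.1
with two genotypes and two environments. Type-I error at the 0.05 level is
nonetheless calibrated (measured 0.04–0.05 under exchangeable nulls with ≥4
replicates per group; heavy ties at 2 replicates per group make it
conservative). Significance calls therefore lean on the bootstrap CI
excluding zero, which is also the decision rule the source analysis states.

## Pipeline

One global seed is fanned out through `numpy.random.SeedSequence` to
independent child streams (simulation, per-species bootstrap, per-species
permutation), so stages are individually reproducible and reruns are
byte-identical. Every run writes a manifest (config hash, seed, version)
beside its outputs. Downstream stages consume only replicate-level
summaries; individual records enter only through the aggregation tallies
and the bootstrap's group totals.

## Problem sizes used by tests and the acceptance script

Simulation-backed checks run at sizes chosen to estimate each quantity to
the precision its tolerance needs: 500 datasets for the bias comparison and
the permutation type-I rate (199 permutations each), 300 datasets for
bootstrap coverage (199 resamples each), 200 datasets for dispersion
calibration, 11 seeds at 100 snails per cell for selection recovery, and
999/999 resamples for the study-scale Cov_GE run.

## Known limitations

- The generator shares one per-cycle probability across both exposure
  cycles; cycle-specific mortality (e.g. injury accumulation) is not
  modelled.
- Body weight influences nothing downstream of the filter; the assay's
  rationale for excluding large snails is size-confounded tolerance, which
  the generator does not simulate.
- Cov_GE with two genotypes and two environments has one degree of freedom
  of pattern: its permutation test has the power floor described above, and
  the estimate is exactly ±1 whenever the cell means are additive,
  regardless of effect magnitude — magnitude lives in the contrast battery,
  not in Cov_GE.
- The mixed-model step some analyses try first (block as a random effect) is
  deliberately out of scope: two blocks cannot support a variance estimate,
  and the fixed-block bias-reduced GLM is the inferential model.
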