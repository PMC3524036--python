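# Methods

## The problem

When three treatments — a placebo (1), an old drug (2) and a new drug
(3) — have each been compared pairwise in separate randomized trials,
the 2-vs-3 contrast can be estimated three ways: directly from the
head-to-head trials (DTC), indirectly through the common comparator
(Bucher's adjusted indirect comparison, AITC), or by combining both
sources (mixed treatment comparison, MTC).  The validity of the
indirect and mixed routes rests on the *consistency* assumption — that
direct and indirect evidence estimate the same quantity.  `nmasim`
simulates closed-loop three-treatment networks of two-arm binomial
trials under controlled amounts of heterogeneity, bias and
inconsistency, and measures how six estimators and three inconsistency
tests behave: type-I error, power, bias and mean squared error over
replicated networks.

## Data-generating model

Each scenario fixes per-contrast trial counts, a common arm size `n`
(default 100), a control-arm risk `P` (default 0.20), true effects
`d_12 = log OR_12` and `d_13 = log OR_13`, a between-trial variance
`tau^2`, and per-contrast bias ratios `ROR_ij`.  For a trial of
contrast (i, j):

1. `d_k ~ Normal(d_ij, tau^2)` — trial-specific effect
   (`d_23 = d_13 - d_12` is always functional, never free);
2. `d_k <- d_k + ln(ROR_ij)` — multiplicative bias on the OR scale.
   `ROR = 0.8` over-states the higher-numbered treatment's effect by
   20%; `ROR = 1` is no bias;
3. treatment-arm risk `P_t = P e^{d_k} / (1 - P + P e^{d_k})`, so that
   `logit(P_t) - logit(P) = d_k` exactly;
4. both arm event counts `~ Binomial(n, risk)`; the control arm is the
   lower-numbered treatment at risk `P`.

Injected inconsistency is a bias applied to the direct 2-3 trials only
(`ror_23 = 0.8` gives a true inconsistency of `ln 0.8 = -0.223` on the
log-ROR scale).  Replicate `c` of a scenario draws from
`SeedSequence(seed, spawn_key=(c,))`, so replicates are independent,
order-free and bitwise reproducible.

**Sign convention.**  Throughout, the effect of contrast (i, j), i < j,
is the log OR of treatment j versus treatment i; the indirect 2-3
estimate is `d_13 - d_12`, and inconsistency is `omega = direct -
indirect`.  For a beneficial outcome (OR < 1), `omega > 0` means the
indirect route over-states the new treatment's benefit.  Equivalent
formulations in the literature differ in the sign of the difference;
this orientation is the one under which the functional-parameter
identity (`OR_23 = 0.75` for `OR_12 = 0.8`, `OR_13 = 0.6`) and the
hierarchical model's `d_bt = d_At - d_Ab` agree.

## Estimators

*Frequentist.*  Per-trial log ORs use the Woolf estimator with variance
`1/a + 1/b + 1/c + 1/d`; if any cell of the 2x2 table is zero, 0.5 is
added to all four cells (Haldane–Anscombe).  Pairwise pooling is
inverse-variance fixed-effect or DerSimonian–Laird random-effects
(moment estimator of `tau^2`, truncated at zero; a single study passes
through with `tau^2 = 0`).  AITC differences the pooled 1-2 and 1-3
estimates and sums their variances; CFMTC pools the direct and indirect
2-3 estimates by inverse variance.  Significance is the two-sided Wald
test at `|Z| > 1.96`, and the inconsistency Z-test uses
`omega / sqrt(Var_dir + Var_ind)` at the same threshold.

*Bayesian.*  Three hierarchical models share a binomial likelihood with
logit link on arm risks: each study `k` has a baseline `mu_k` on its
base (lower-numbered) treatment and a relative effect on the other arm.

- **CBMTC** (consistency): basic parameters `d_AB`, `d_AC`; the 2-3
  mean is constrained to `d_AC - d_AB`.  Random flavor:
  `delta_k ~ Normal(d_bt, tau^2)` with `tau ~ Uniform(0, 2)`; fixed
  flavor sets `tau^2 = 0`.
- **RIBMTC** (random inconsistency): the 2-3 mean is
  `d_AC - d_AB + omega` with `omega ~ Normal(0, sigma_omega^2)` and
  `sigma_omega ~ Uniform(0, 2)`.
- **IBMA** (inconsistency meta-analysis): `d_AB`, `d_AC`, `d_BC` all
  free with a shared `tau^2`; node-splitting computes
  `omega = d_BC - (d_AC - d_AB)` draw by draw.

Priors default to `Normal(0, 100^2)` for effects and baselines, and the
uniform bounds above for the between-study and inconsistency standard
deviations; the uniform upper bound 2 comfortably covers the simulated
`tau^2 <= 0.15`.  Credible intervals are equal-tailed 2.5/97.5
percentile intervals, and "significant" means the interval excludes
zero.  A quantity's posterior summary carries its mean, sd, interval,
effective sample size and split-R-hat.

## The sampler

Inference uses a self-contained adaptive random-walk
Metropolis-within-Gibbs sampler.  Study baselines and trial effects are
updated element-wise (the likelihood factorizes over studies); pooled
effects, `tau` and `sigma_omega` are scalar updates; proposal scales
adapt toward 44% acceptance in 50-iteration batches during burn-in.
Two joint translation moves are essential for acceptable mixing along
the posterior's ridge directions: in the random flavor an effect and
the trial effects that depend on it move together (leaving the
random-effects density invariant), and in the fixed flavor an effect
moves with a compensating half-shift of the affected studies'
baselines.  Without these, single-coordinate moves produce effective
sample sizes an order of magnitude smaller and visibly biased short
runs.

Initial values come from empirical logits; `tau` and `sigma_omega`
start inside their uniform supports (at half the upper bound when the
bound is small — proposals outside the support are rejected, so a
start outside it would never recover).  Default chain settings are
20,000 burn-in and 40,000 sampling iterations thinned 5:1 (8,000
retained draws); replicated desk-scale runs in the test suite use 300
burn-in / 900 kept, which the joint moves make adequate for posterior
means (ESS of order 100 per fit).  Low ESS (< 100 per chain) or
split-R-hat > 1.05 triggers a `RuntimeWarning`; fits are flagged, never
silently discarded.

## Performance harness

`run_scenario` simulates each replicate, fits the requested methods in
fixed and/or random flavors, and records the 2-3 estimate, its
significance, and the inconsistency estimate where the method has one
(the Bucher Z-test statistic is recorded on the AITC rows; RIBMTC
contributes its posterior `omega`; IBMA its node-split `omega`).
Aggregation reports bias `mean(est - truth)`, MSE
`mean((est - truth)^2)`, rejection rate (type-I error when the
generating truth is zero, power otherwise) and the Monte-Carlo 95%
interval — the 2.5/97.5 percentile range of the per-replicate values,
computed with numpy's linear-interpolation quantile rule.  The truth
for the effect is the scenario's unbiased `d_23`; for inconsistency it
is `ln ror_23 + ln ror_12 - ln ror_13`.  Per-replicate fitting failures
are logged and counted, not fatal.

## Numerical findings worth knowing

- **Small-sample attenuation.**  At 100 patients/arm and a 20% control
  risk, the tabulated log OR is attenuated toward zero by roughly +0.02
  for a true log OR of -0.29, and inverse-variance weighting adds a
  weight-estimate correlation in the same direction.  The mean Bucher
  inconsistency estimate under an injected `ln ROR = -0.223` is
  therefore about -0.20 rather than -0.223 at this arm size; the
  attenuation shrinks with arm size and largely cancels between the
  direct and indirect components.  This is a property of the prescribed
  estimators, not of the generator.
- **Singleton networks.**  With one trial per contrast, the
  random-flavor posteriors are dominated by the uniform prior on `tau`;
  2-3 intervals always span zero, so rejection rates are exactly 0.
  This is the expected degenerate behavior, not a sampler failure.
- **Replicate counts.**  The test suite uses 500 frequentist and ~100
  Bayesian replicates per scenario (25-30 for the slowest regimes), the
  acceptance script 1000; these are the package's desk-scale choices,
  with Monte-Carlo error bars widened accordingly.  Full-scale runs
  (5,000 replicates, full-length chains) use the same code paths via
  `ScenarioConfig.n_reps` and `MCMCSettings`.

## What the generator does and does not emulate

It emulates: trial-level heterogeneity of log ORs, binomial sampling
noise, multiplicative bias per contrast, and loop inconsistency via
biased direct evidence.  It does not emulate: multi-arm trials,
networks beyond three treatments, unequal arm sizes, non-binary
outcomes, baseline-risk variation across trials, or effect modifiers —
so passing tests say nothing about those features of real evidence
networks.  All trials within a scenario share one control-arm risk;
real networks vary.

## Known limitations

- The frequentist significance rule uses the fixed 1.96 threshold, not
  study-count-adjusted critical values.
- Split-R-hat is the plain (not rank-normalized) formula, computed by
  halving chains; ESS comes from `arviz`.
- The IBMA model shares one `tau^2` across contrasts (by construction);
  contrast-specific heterogeneity is out of scope.
- Lumley's frequentist network method and covariate meta-regression are
  deliberately excluded.
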