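# nmasim

Simulation evaluation of indirect and mixed treatment comparison
methods on three-treatment networks of two-arm binomial trials.

When a new drug (treatment 3) has been compared with an old drug
(treatment 2) only rarely head-to-head, but both have been compared
with placebo (treatment 1), the 2-vs-3 effect can be estimated
directly (DTC), indirectly through the common comparator (Bucher's
adjusted indirect comparison, AITC — `d_23^ind = d_13 - d_12`,
`Var = Var(d_13) + Var(d_12)`), or by mixing both (MTC / network
meta-analysis).  Those routes are only as good as the *consistency*
assumption linking direct and indirect evidence.  `nmasim` is for
methodologists who want to measure — by Monte-Carlo simulation — the
type-I error, power, bias and MSE of these estimators, and of the
tests meant to detect inconsistency, under controlled heterogeneity
(`tau^2`), trial-level bias (ratio of odds ratios, ROR) and injected
loop inconsistency.

Six estimators are implemented: pooled direct comparison (fixed-effect
inverse-variance and DerSimonian–Laird random-effects), Bucher AITC,
frequentist consistency MTC, and three Bayesian hierarchical models
fitted by a built-in adaptive Metropolis-within-Gibbs sampler —
consistency MTC (`d_BC = d_AC - d_AB`), random-inconsistency MTC
(`d_BC = d_AC - d_AB + omega`, `omega ~ N(0, sigma_omega^2)`), and
inconsistency Bayesian meta-analysis with node-splitting.
Inconsistency is tested by the frequentist Z statistic
`omega / sqrt(Var_dir + Var_ind)` at `|Z| > 1.96` or by 95% credible
intervals excluding zero.  See `docs/methods.md` for the full model
descriptions and numerical choices.

## Worked example

Evaluate the frequentist methods on a no-bias scenario — 20 trials per
contrast, 100 patients per arm, 20% control risk, OR12 = 0.8,
OR13 = 0.6 (so the true OR23 = 0.75), between-trial variance 0.05 —
over 500 replicate networks:

```python
import math
import nmasim as nm

sc = nm.ScenarioConfig(
    n_studies_12=20, n_studies_13=20, n_studies_23=20,
    tau2=0.05, true_logor_13=math.log(0.6), seed=42, n_reps=500, name="demo",
)
run = nm.run_scenario(sc, methods=("DTC", "AITC", "CFMTC"), models=("random",))
print(run.summarize().round(4).to_string(index=False))
```

```
method      quantity  n_reps  true_value    bias    mse  rejection_rate  mc_low  mc_high
   DTC        effect     500     -0.2877  0.0163 0.0090           0.800 -0.4439  -0.0788
  AITC        effect     500     -0.2877 -0.0037 0.0179           0.546 -0.5785  -0.0447
  AITC inconsistency     500      0.0000  0.0200 0.0271           0.038 -0.3033   0.3433
 CFMTC        effect     500     -0.2877  0.0108 0.0061           0.930 -0.4313  -0.1209
```

Reading this: all three estimators are essentially unbiased for the
true log OR23 of -0.288 (their Monte-Carlo 95% intervals, `mc_low` to
`mc_high`, easily cover small biases).  The indirect comparison pays
for its two-step construction with double the MSE of the direct one
(0.018 vs 0.009) and lower power (55% vs 80%), while mixing direct and
indirect evidence raises power to 93% with the smallest MSE.  With no
inconsistency injected, the Bucher Z-test's rejection rate (0.038) sits
near its nominal 5% level.

Bayesian fits work on the same networks:

```python
data = nm.MTCData.from_network(nm.simulate_network(sc, 0))
fit = nm.fit_consistency_bmtc(data, model="random")   # full-length default chains
print(fit.summary("d_BC"))
```

The command line mirrors the library: `nmasim simulate` writes a
replicate network as CSV, `nmasim fit` runs one method on a trial
table (simulated or your own, wide or long format), `nmasim evaluate`
runs a replicated scenario, and `nmasim grid` expands a YAML grid file
(list-valued fields become a Cartesian product) and evaluates every
cell.

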