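"""Replicated simulation runs and performance metrics.

For every replicate network the harness fits the requested comparison
methods in fixed-effect and/or random-effects flavors and records the
2-3 treatment-effect estimate with its significance flag, plus the
inconsistency estimate where the method provides one:

* ``DTC``   — pooled head-to-head 2-3 trials;
* ``AITC``  — Bucher indirect estimate via treatment 1; its rows also
  carry the Bucher inconsistency Z-test (omega_hat, omega_significant),
  since that statistic is the direct-vs-indirect contrast;
* ``CFMTC`` — inverse-variance combination of DTC and AITC;
* ``CBMTC`` — consistency Bayesian MTC (no inconsistency estimate);
* ``RIBMTC``— random-inconsistency Bayesian MTC (posterior omega);
* ``IBMA``  — inconsistency Bayesian meta-analysis (node-split omega).

Performance over replicates is summarized by bias, MSE, rejection rate
(type-I error when the generating truth is null, power otherwise) and
the Monte-Carlo 2.5/97.5 percentile interval of the estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import bayes
from .comparisons import (
    bucher_indirect,
    consistency_frequentist_mtc,
    from_meta,
    inconsistency_z_test,
)
from .pairwise import pool, table_logor
from .scenarios import ScenarioConfig
from .simulate import TrialNetwork, simulate_network

logger = logging.getLogger(__name__)

FREQUENTIST_METHODS = ("DTC", "AITC", "CFMTC")
BAYESIAN_METHODS = ("CBMTC", "RIBMTC", "IBMA")
ALL_METHODS = FREQUENTIST_METHODS + BAYESIAN_METHODS

_BAYES_FITTERS = {
    "CBMTC": bayes.fit_consistency_bmtc,
    "RIBMTC": bayes.fit_random_inconsistency_bmtc,
    "IBMA": bayes.fit_ibma,
}


# ---------------------------------------------------------------------------
# Scalar performance metrics


def bias_estimate(estimates, true_value: float) -> float:
    """Mean of (estimate - truth) over replicates."""
    estimates = np.asarray(list(estimates), dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.mean(estimates - true_value))


def mse_estimate(estimates, true_value: float) -> float:
    """Mean of (estimate - truth)^2 over replicates."""
    estimates = np.asarray(list(estimates), dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.mean((estimates - true_value) ** 2))


def rejection_rate(flags) -> float:
    """Fraction of replicates whose test rejected the null."""
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("no significance flags")
    return float(np.mean(flags))


def monte_carlo_interval(estimates) -> tuple[float, float]:
    """Empirical 2.5th/97.5th percentiles (linear-interpolation rule)."""
    estimates = np.asarray(list(estimates), dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    lo, hi = np.quantile(estimates, [0.025, 0.975])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Replicate-level fitting


def _frequentist_rows(network: TrialNetwork, methods, models) -> list[dict]:
    by_contrast = {
        c: [table_logor(t) for t in network.trials_for(c)]
        for c in ((1, 2), (1, 3), (2, 3))
    }
    rows = []
    for model in models:
        pooled = {
            c: from_meta(pool(est, model), "direct")
            for c, est in by_contrast.items()
            if est
        }
        direct = pooled.get((2, 3))
        indirect = None
        if (1, 2) in pooled and (1, 3) in pooled:
            indirect = bucher_indirect(pooled[(1, 2)], pooled[(1, 3)])
        if "DTC" in methods:
            if direct is None:
                raise ValueError("DTC requires 2-3 trials")
            rows.append(
                dict(method="DTC", model=model, estimate=direct.logor,
                     significant=direct.significant, omega_hat=np.nan,
                     omega_significant=None)
            )
        if "AITC" in methods:
            if indirect is None:
                raise ValueError("AITC requires 1-2 and 1-3 trials")
            omega_hat, omega_sig = np.nan, None
            if direct is not None:
                zres = inconsistency_z_test(direct, indirect)
                omega_hat, omega_sig = zres.omega, zres.significant
            rows.append(
                dict(method="AITC", model=model, estimate=indirect.logor,
                     significant=indirect.significant, omega_hat=omega_hat,
                     omega_significant=omega_sig)
            )
        if "CFMTC" in methods:
            if direct is None or indirect is None:
                raise ValueError("CFMTC requires all three contrasts")
            mixed = consistency_frequentist_mtc(direct, indirect)
            rows.append(
                dict(method="CFMTC", model=model, estimate=mixed.logor,
                     significant=mixed.significant, omega_hat=np.nan,
                     omega_significant=None)
            )
    return rows


def _bayesian_rows(
    network: TrialNetwork, methods, models, priors, mcmc: bayes.MCMCSettings
) -> list[dict]:
    data = bayes.MTCData.from_network(network)
    rows = []
    for model in models:
        for mi, method in enumerate(m for m in BAYESIAN_METHODS if m in methods):
            ss = np.random.SeedSequence(
                entropy=network.scenario.seed,
                spawn_key=(network.replicate_index, 1 + mi, models.index(model)),
            )
            seed = int(ss.generate_state(1)[0] % (2**31))
            fit = _BAYES_FITTERS[method](
                data,
                priors=priors,
                settings=dc_replace(mcmc, seed=seed),
                model=model,
                check_ess=False,
            )
            d_bc = fit.summary("d_BC")
            omega_hat, omega_sig = np.nan, None
            if method == "RIBMTC":
                om = fit.summary("omega_BC")
                omega_hat, omega_sig = om.mean, om.significant
            elif method == "IBMA":
                om = bayes.node_split_inconsistency(fit)
                omega_hat, omega_sig = om.mean, om.significant
            rows.append(
                dict(method=method, model=model, estimate=d_bc.mean,
                     significant=d_bc.significant, omega_hat=omega_hat,
                     omega_significant=omega_sig)
            )
    return rows


@dataclass
class ScenarioRun:
    """Replicate-level results of one scenario plus bookkeeping."""

    scenario: ScenarioConfig
    replicates: pd.DataFrame
    n_failures: int

    def summarize(
        self, true_theta: float | None = None, true_omega: float | None = None
    ) -> pd.DataFrame:
        return summarize(self, true_theta=true_theta, true_omega=true_omega)


def run_scenario(
    scenario: ScenarioConfig,
    methods=FREQUENTIST_METHODS,
    models=("fixed", "random"),
    priors: bayes.PriorSpec | None = None,
    mcmc: bayes.MCMCSettings | None = None,
    n_reps: int | None = None,
) -> ScenarioRun:
    """Simulate and fit ``n_reps`` replicate networks of a scenario.

    Per-replicate fitting failures are logged and counted, not fatal;
    the replicate table simply lacks those rows.  Bayesian methods use
    ``mcmc`` chain settings (full-length defaults if omitted) with a
    per-replicate seed derived from the scenario seed.
    """
    n_reps = scenario.n_reps if n_reps is None else n_reps
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    methods = tuple(methods)
    models = tuple(models)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    mcmc = mcmc or bayes.MCMCSettings()
    want_bayes = any(m in BAYESIAN_METHODS for m in methods)

    rows: list[dict] = []
    n_failures = 0
    for c in range(n_reps):
        network = simulate_network(scenario, c)
        try:
            rep_rows = _frequentist_rows(network, methods, models)
            if want_bayes:
                rep_rows += _bayesian_rows(network, methods, models, priors, mcmc)
        except Exception:
            logger.exception("replicate %d failed", c)
            n_failures += 1
            continue
        for r in rep_rows:
            r["replicate"] = c
        rows.extend(rep_rows)
    cols = ["replicate", "method", "model", "estimate", "significant",
            "omega_hat", "omega_significant"]
    replicates = pd.DataFrame(rows, columns=cols)
    return ScenarioRun(scenario, replicates, n_failures)


def summarize(
    run: ScenarioRun,
    true_theta: float | None = None,
    true_omega: float | None = None,
) -> pd.DataFrame:
    """Aggregate a ScenarioRun into per-method performance rows.

    Two quantity families are summarized: the 2-3 treatment effect
    ("effect", truth = the scenario's unbiased true log OR) and the
    inconsistency estimate ("inconsistency", truth = the injected
    log ROR) for methods that produce one.
    """
    scenario = run.scenario
    theta = scenario.true_logor_23 if true_theta is None else true_theta
    omega = scenario.true_omega if true_omega is None else true_omega
    out = []
    for (method, model), grp in run.replicates.groupby(["method", "model"], sort=False):
        est = grp["estimate"].to_numpy(dtype=float)
        lo, hi = monte_carlo_interval(est)
        out.append(
            dict(
                scenario=scenario.name,
                method=method,
                model=model,
                quantity="effect",
                n_reps=len(grp),
                true_value=theta,
                bias=bias_estimate(est, theta),
                mse=mse_estimate(est, theta),
                rejection_rate=rejection_rate(grp["significant"].astype(bool)),
                mc_low=lo,
                mc_high=hi,
                metric_role="type_I_error" if theta == 0 else "power",
            )
        )
        om = grp["omega_hat"].to_numpy(dtype=float)
        om_ok = np.isfinite(om)
        if om_ok.any():
            flags = grp.loc[om_ok, "omega_significant"].astype(bool)
            lo, hi = monte_carlo_interval(om[om_ok])
            out.append(
                dict(
                    scenario=scenario.name,
                    method=method,
                    model=model,
                    quantity="inconsistency",
                    n_reps=int(om_ok.sum()),
                    true_value=omega,
                    bias=bias_estimate(om[om_ok], omega),
                    mse=mse_estimate(om[om_ok], omega),
                    rejection_rate=rejection_rate(flags),
                    mc_low=lo,
                    mc_high=hi,
                    metric_role="type_I_error" if omega == 0 else "power",
                )
            )
    return pd.DataFrame(out)
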