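"""Independent brute-force oracles and hand-computed fixtures.

Everything here is deliberately naive — literal transcriptions of the
pooling formulas and a grid-integration posterior — so the test suite
can cross-check the production implementations against code that shares
nothing with them.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.special import logsumexp


def oracle_inverse_variance(estimates) -> tuple[float, float]:
    """Naive-loop inverse-variance pooling: returns (pooled, variance).

    ``estimates`` is a sequence of (logor, variance) pairs.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates")
    sw = 0.0
    swd = 0.0
    for logor, var in estimates:
        w = 1.0 / var
        sw += w
        swd += w * logor
    return swd / sw, 1.0 / sw


def oracle_dersimonian_laird(estimates) -> tuple[float, float, float]:
    """Naive DerSimonian-Laird pooling: returns (pooled, variance, tau2).

    Literal transcription: Q with fixed-effect weights, moment estimator
    truncated at zero, then inverse-variance with inflated variances.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates")
    k = len(estimates)
    if k == 1:
        logor, var = estimates[0]
        return logor, var, 0.0
    d_fe, _ = oracle_inverse_variance(estimates)
    q = 0.0
    sw = 0.0
    sw2 = 0.0
    for logor, var in estimates:
        w = 1.0 / var
        q += w * (logor - d_fe) ** 2
        sw += w
        sw2 += w * w
    c = sw - sw2 / sw
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    pooled, variance = oracle_inverse_variance(
        [(logor, var + tau2) for logor, var in estimates]
    )
    return pooled, variance, tau2


def oracle_exact_posterior_grid(
    events_ctrl: int,
    n_ctrl: int,
    events_trt: int,
    n_trt: int,
    effect_prior_sd: float = 100.0,
    baseline_prior_sd: float = 100.0,
    n_grid: int = 601,
) -> dict:
    """Grid-integrated posterior of the log OR for one two-arm trial.

    Model: events ~ Binomial with logit(p_ctrl) = mu and
    logit(p_trt) = mu + d, with independent normal priors on mu and d.
    The joint posterior is evaluated on a 2-D grid and the d margin is
    returned with its mean and sd, for validating the MCMC sampler.
    """
    mu_hat = math.log((events_ctrl + 0.5) / (n_ctrl - events_ctrl + 0.5))
    d_hat = (
        math.log((events_trt + 0.5) / (n_trt - events_trt + 0.5)) - mu_hat
    )
    mu_se = math.sqrt(
        1.0 / (events_ctrl + 0.5) + 1.0 / (n_ctrl - events_ctrl + 0.5)
    )
    d_se = math.sqrt(
        mu_se**2
        + 1.0 / (events_trt + 0.5)
        + 1.0 / (n_trt - events_trt + 0.5)
    )
    # Window each axis around the precision-weighted (likelihood x prior)
    # normal approximation so the grid resolves the posterior mass for
    # vague and tight priors alike.
    def _window(center: float, se: float, prior_sd: float):
        prec = 1.0 / se**2 + 1.0 / prior_sd**2
        post_mean = (center / se**2) / prec
        post_sd = prec**-0.5
        return post_mean - 10 * post_sd, post_mean + 10 * post_sd

    mu = np.linspace(*_window(mu_hat, mu_se, baseline_prior_sd), n_grid)
    d = np.linspace(*_window(d_hat, d_se, effect_prior_sd), n_grid)
    mu_g, d_g = np.meshgrid(mu, d, indexing="ij")

    def binom_ll(r, n, eta):
        return r * eta - n * np.logaddexp(0.0, eta)

    logpost = (
        binom_ll(events_ctrl, n_ctrl, mu_g)
        + binom_ll(events_trt, n_trt, mu_g + d_g)
        - 0.5 * (mu_g / baseline_prior_sd) ** 2
        - 0.5 * (d_g / effect_prior_sd) ** 2
    )
    log_marg_d = logsumexp(logpost, axis=0)
    log_marg_d -= logsumexp(log_marg_d)
    dens = np.exp(log_marg_d)
    dens /= dens.sum()
    mean = float(np.sum(d * dens))
    sd = float(math.sqrt(np.sum((d - mean) ** 2 * dens)))
    return {"grid": d, "density": dens, "mean": mean, "sd": sd}


# ---------------------------------------------------------------------------
# Hand-computed 2x2 fixture tables.  Each row carries the derivation of its
# expected values so the numbers can be re-checked by hand.

FIXTURE_TABLES: list[dict] = [
    {
        "name": "identical_arms",
        "events_ctrl": 20, "n_ctrl": 100, "events_trt": 20, "n_trt": 100,
        "logor": 0.0,
        "variance": 0.125,
        "derivation": "ln((20/80)/(20/80))=0; 1/20+1/80+1/20+1/80=0.125",
    },
    {
        "name": "modest_benefit",
        "events_ctrl": 20, "n_ctrl": 100, "events_trt": 16, "n_trt": 100,
        "logor": math.log((16 / 84) / (20 / 80)),  # -0.2719337...
        "variance": 1 / 16 + 1 / 84 + 1 / 20 + 1 / 80,  # 0.1369048
        "derivation": "ln((16/84)/(20/80)); 1/16+1/84+1/20+1/80",
    },
    {
        "name": "zero_cell_continuity",
        "events_ctrl": 0, "n_ctrl": 100, "events_trt": 10, "n_trt": 100,
        "logor": math.log((10.5 / 90.5) / (0.5 / 100.5)),
        "variance": 1 / 10.5 + 1 / 90.5 + 1 / 0.5 + 1 / 100.5,
        "derivation": "0.5 added to all four cells: (10.5,90.5) vs (0.5,100.5)",
    },
    {
        "name": "strong_benefit",
        "events_ctrl": 30, "n_ctrl": 100, "events_trt": 15, "n_trt": 100,
        "logor": math.log((15 / 85) / (30 / 70)),  # -0.8873...
        "variance": 1 / 15 + 1 / 85 + 1 / 30 + 1 / 70,
        "derivation": "ln((15/85)/(30/70)); 1/15+1/85+1/30+1/70",
    },
]


def write_fixture_csv(path: str | Path) -> None:
    """Write the hand-computed fixture tables as a plain CSV."""
    import pandas as pd

    pd.DataFrame(FIXTURE_TABLES).to_csv(path, index=False)
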