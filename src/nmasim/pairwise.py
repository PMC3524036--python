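"""Per-trial log odds ratios and pairwise meta-analysis pooling.

Provides the Woolf log OR with its large-sample variance (with the
Haldane–Anscombe 0.5 continuity correction when any 2x2 cell is zero),
fixed-effect inverse-variance pooling, and DerSimonian–Laird
random-effects pooling.  These are the frequentist building blocks for
the direct and (via Bucher's adjustment) indirect comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .simulate import Trial


@dataclass(frozen=True)
class StudyEstimate:
    """Log OR and variance from one trial's 2x2 table."""

    logor: float
    variance: float
    study_id: str | None = None
    contrast: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled log OR for one contrast under one pooling model."""

    logor: float
    variance: float
    model: str  # "fixed" | "random"
    tau2_hat: float
    k_studies: int
    contrast: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.tau2_hat < 0:
            raise ValueError("tau2_hat must be nonnegative")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")


def table_logor(trial: Trial) -> StudyEstimate:
    """Woolf log OR of the treatment (higher-numbered) arm vs control.

    If any of the four cells (events or non-events in either arm) is
    zero, 0.5 is added to all four cells of the table before computing,
    keeping the estimate and its variance finite.
    """
    if trial.n_ctrl <= 0 or trial.n_trt <= 0:
        raise ValueError("both arms must have positive totals")
    a = float(trial.events_trt)
    b = float(trial.n_trt - trial.events_trt)
    c = float(trial.events_ctrl)
    d = float(trial.n_ctrl - trial.events_ctrl)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    logor = math.log((a * d) / (b * c))
    variance = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return StudyEstimate(logor, variance, trial.study_id, trial.contrast)


def _check(estimates) -> list[StudyEstimate]:
    estimates = list(estimates)
    if not estimates:
        raise ValueError("at least one study estimate is required")
    contrasts = {e.contrast for e in estimates if e.contrast is not None}
    if len(contrasts) > 1:
        raise ValueError(f"estimates mix contrasts: {sorted(contrasts)}")
    return estimates


def fixed_effect_pool(estimates) -> MetaResult:
    """Inverse-variance fixed-effect pooling; k = 1 passes through."""
    estimates = _check(estimates)
    weights = [1.0 / e.variance for e in estimates]
    sw = sum(weights)
    pooled = sum(w * e.logor for w, e in zip(weights, estimates)) / sw
    contrast = estimates[0].contrast
    return MetaResult(pooled, 1.0 / sw, "fixed", 0.0, len(estimates), contrast)


def dersimonian_laird_pool(estimates) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    tau^2 is estimated from Cochran's Q with fixed-effect weights and
    truncated at zero; k = 1 degenerates to the single study with
    tau2_hat = 0.
    """
    estimates = _check(estimates)
    k = len(estimates)
    contrast = estimates[0].contrast
    if k == 1:
        e = estimates[0]
        return MetaResult(e.logor, e.variance, "random", 0.0, 1, contrast)
    w = [1.0 / e.variance for e in estimates]
    sw = sum(w)
    d_fe = sum(wi * e.logor for wi, e in zip(w, estimates)) / sw
    q = sum(wi * (e.logor - d_fe) ** 2 for wi, e in zip(w, estimates))
    c = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = [1.0 / (e.variance + tau2) for e in estimates]
    sw_star = sum(w_star)
    pooled = sum(wi * e.logor for wi, e in zip(w_star, estimates)) / sw_star
    return MetaResult(pooled, 1.0 / sw_star, "random", tau2, k, contrast)


def pool(estimates, model: str) -> MetaResult:
    """Dispatch to fixed-effect or DerSimonian–Laird pooling."""
    if model == "fixed":
        return fixed_effect_pool(estimates)
    if model == "random":
        return dersimonian_laird_pool(estimates)
    raise ValueError("model must be 'fixed' or 'random'")
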