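"""Generation of replicate networks of two-arm binomial trials.

Each simulated trial of contrast (i, j), i < j, is produced in four
steps:

1. draw the trial-specific log OR ``d_k ~ Normal(d_ij, tau^2)``;
2. add ``ln(ROR_ij)`` — multiplicative bias on the OR scale, directed so
   that ROR < 1 over-states the benefit of the higher-numbered (newer)
   treatment;
3. convert the control-arm risk ``p`` to the treatment-arm risk
   ``p e^d / (1 - p + p e^d)``;
4. draw both arm event counts from Binomial(n_per_arm, risk).

The control ("ctrl") arm is always the lower-numbered treatment and its
risk is the scenario's baseline risk.  Replicates are reproducible and
order-independent: replicate ``c`` of a scenario uses the stream
``SeedSequence(scenario.seed, spawn_key=(c,))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scenarios import CONTRASTS, ScenarioConfig


@dataclass(frozen=True)
class Trial:
    """One simulated (or user-supplied) two-arm trial."""

    study_id: str
    contrast: tuple[int, int]
    events_ctrl: int
    n_ctrl: int
    events_trt: int
    n_trt: int

    def __post_init__(self) -> None:
        if tuple(self.contrast) not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if not (0 <= self.events_ctrl <= self.n_ctrl):
            raise ValueError("control-arm events must lie in [0, n_ctrl]")
        if not (0 <= self.events_trt <= self.n_trt):
            raise ValueError("treatment-arm events must lie in [0, n_trt]")


@dataclass(frozen=True)
class TrialNetwork:
    """A replicate: the full set of trials simulated under one scenario."""

    trials: tuple[Trial, ...]
    scenario: ScenarioConfig
    replicate_index: int

    def trials_for(self, contrast: tuple[int, int]) -> list[Trial]:
        c = tuple(contrast)
        return [t for t in self.trials if t.contrast == c]


def draw_trial_logor(true_logor: float, tau2: float, rng: np.random.Generator) -> float:
    """Draw a trial-specific log OR from Normal(true_logor, tau2).

    With ``tau2 == 0`` the true value is returned exactly (no stream
    consumption), so zero-heterogeneity scenarios are fully degenerate.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    if tau2 == 0:
        return float(true_logor)
    return float(rng.normal(true_logor, math.sqrt(tau2)))


def apply_bias(logor: float, ror: float) -> float:
    """Shift a log OR by ln(ROR); the biased OR equals OR * ROR."""
    if ror <= 0:
        raise ValueError("ror must be positive")
    return float(logor + math.log(ror))


def risk_from_logor(p_baseline: float, logor: float) -> float:
    """Treatment-arm risk implied by a control risk and a log OR.

    ``P_t = P e^d / (1 - P + P e^d)`` — the logistic transform that makes
    ``logit(P_t) - logit(P) = d`` exactly.
    """
    if not 0.0 < p_baseline < 1.0:
        raise ValueError("p_baseline must lie strictly in (0, 1)")
    odds = p_baseline / (1.0 - p_baseline) * math.exp(logor)
    return float(odds / (1.0 + odds))


def generating_logor(
    scenario: ScenarioConfig, contrast: tuple[int, int], biased: bool = True
) -> float:
    """Mean of the trial-specific log OR distribution for a contrast.

    This is the scenario's true log OR (the 2-3 contrast being the
    functional parameter) plus, when ``biased``, the contrast's ln(ROR).
    """
    d = scenario.true_logor(contrast)
    if biased:
        d = apply_bias(d, scenario.ror(contrast))
    return d


def simulate_trial(
    contrast: tuple[int, int],
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    study_id: str = "",
) -> Trial:
    """Simulate one two-arm trial of the given contrast.

    Draw order is fixed (heterogeneity draw, control arm, treatment arm)
    so seeded streams reproduce bitwise.
    """
    contrast = tuple(contrast)
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    d = draw_trial_logor(scenario.true_logor(contrast), scenario.tau2, rng)
    d = apply_bias(d, scenario.ror(contrast))
    p_trt = risk_from_logor(scenario.baseline_risk, d)
    n = scenario.n_per_arm
    events_ctrl = int(rng.binomial(n, scenario.baseline_risk))
    events_trt = int(rng.binomial(n, p_trt))
    return Trial(
        study_id=study_id or f"{contrast[0]}{contrast[1]}",
        contrast=contrast,
        events_ctrl=events_ctrl,
        n_ctrl=n,
        events_trt=events_trt,
        n_trt=n,
    )


def replicate_rng(scenario: ScenarioConfig, replicate_index: int) -> np.random.Generator:
    """Independent, order-free random stream for one replicate."""
    ss = np.random.SeedSequence(entropy=scenario.seed, spawn_key=(replicate_index,))
    return np.random.default_rng(ss)


def simulate_network(scenario: ScenarioConfig, replicate_index: int = 0) -> TrialNetwork:
    """Simulate the full closed-loop network for one replicate."""
    rng = replicate_rng(scenario, replicate_index)
    trials: list[Trial] = []
    for contrast in CONTRASTS:
        for k in range(scenario.n_studies(contrast)):
            sid = f"{contrast[0]}{contrast[1]}-{k + 1:03d}"
            trials.append(simulate_trial(contrast, scenario, rng, study_id=sid))
    return TrialNetwork(tuple(trials), scenario, replicate_index)


# ---------------------------------------------------------------------------
# Tabular import/export

WIDE_COLUMNS = ["study_id", "treat_a", "treat_b", "events_a", "n_a", "events_b", "n_b"]


def network_to_frame(network: TrialNetwork) -> pd.DataFrame:
    """Wide long-format table: one row per trial, ctrl arm = treat_a."""
    rows = [
        {
            "study_id": t.study_id,
            "treat_a": t.contrast[0],
            "treat_b": t.contrast[1],
            "events_a": t.events_ctrl,
            "n_a": t.n_ctrl,
            "events_b": t.events_trt,
            "n_b": t.n_trt,
        }
        for t in network.trials
    ]
    return pd.DataFrame(rows, columns=WIDE_COLUMNS)


def trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    """Build trials from a wide (one row/trial) or long (one row/arm) table.

    The long format has columns study_id, treatment, events, total with
    exactly two rows per study; the lower-numbered treatment is taken as
    the control arm.
    """
    cols = set(df.columns)
    if {"treat_a", "treat_b"} <= cols:
        trials = []
        for row in df.itertuples(index=False):
            a, b = int(row.treat_a), int(row.treat_b)
            if a > b:  # normalize so ctrl is lower-numbered
                a, b = b, a
                ea, na, eb, nb = row.events_b, row.n_b, row.events_a, row.n_a
            else:
                ea, na, eb, nb = row.events_a, row.n_a, row.events_b, row.n_b
            trials.append(
                Trial(str(row.study_id), (a, b), int(ea), int(na), int(eb), int(nb))
            )
        return trials
    if {"study_id", "treatment", "events", "total"} <= cols:
        trials = []
        for sid, grp in df.groupby("study_id", sort=False):
            if len(grp) != 2:
                raise ValueError(f"study {sid!r} must have exactly two arms")
            grp = grp.sort_values("treatment")
            (t1, e1, n1), (t2, e2, n2) = grp[["treatment", "events", "total"]].to_numpy()
            trials.append(Trial(str(sid), (int(t1), int(t2)), int(e1), int(n1), int(e2), int(n2)))
        return trials
    raise ValueError("unrecognized trial table columns")


def read_trials(path: str | Path) -> list[Trial]:
    """Read trials from a delimited file in wide or long format."""
    return trials_from_frame(pd.read_csv(path))


def write_network(network: TrialNetwork, path: str | Path) -> None:
    network_to_frame(network).to_csv(path, index=False)
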