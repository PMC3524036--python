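"""Scenario configuration for simulated three-treatment trial networks.

A scenario describes one cell of the simulation grid: how many two-arm
trials compare each pair of the three treatments (1 = placebo, 2 = old
drug, 3 = new drug), the arm size, the control-arm event risk, the true
log odds ratios, the between-trial variance tau^2, and any multiplicative
bias (ratio of odds ratios, ROR) injected per contrast.

The contrast 2-vs-3 effect is always a functional parameter:
``true_logor_23 = true_logor_13 - true_logor_12``.  Throughout the
package the log OR of a contrast (i, j) with i < j is the log odds ratio
of treatment j relative to treatment i, so a negative value means the
higher-numbered treatment reduces the event risk.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

#: The three contrasts of the closed loop, in canonical order.
CONTRASTS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class ScenarioConfig:
    """Input parameters for one simulation scenario.

    Defaults reproduce the base simulation conditions: 100 patients per
    arm, 20% control-arm risk, OR12 = 0.8, no heterogeneity, no bias.
    """

    n_studies_12: int = 20
    n_studies_13: int = 20
    n_studies_23: int = 20
    n_per_arm: int = 100
    baseline_risk: float = 0.2
    true_logor_12: float = math.log(0.8)
    true_logor_13: float = math.log(0.8)
    tau2: float = 0.0
    ror_12: float = 1.0
    ror_13: float = 1.0
    ror_23: float = 1.0
    n_reps: int = 5000
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        for attr in ("n_studies_12", "n_studies_13", "n_studies_23"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be nonnegative")
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must lie strictly in (0, 1)")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        for attr in ("ror_12", "ror_13", "ror_23"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive (1.0 means no bias)")
        if self.n_reps <= 0:
            raise ValueError("n_reps must be positive")

    @property
    def true_logor_23(self) -> float:
        """Functional parameter: log OR of treatment 3 vs 2, never free."""
        return self.true_logor_13 - self.true_logor_12

    def n_studies(self, contrast: tuple[int, int]) -> int:
        return {
            (1, 2): self.n_studies_12,
            (1, 3): self.n_studies_13,
            (2, 3): self.n_studies_23,
        }[tuple(contrast)]

    def true_logor(self, contrast: tuple[int, int]) -> float:
        return {
            (1, 2): self.true_logor_12,
            (1, 3): self.true_logor_13,
            (2, 3): self.true_logor_23,
        }[tuple(contrast)]

    def ror(self, contrast: tuple[int, int]) -> float:
        return {
            (1, 2): self.ror_12,
            (1, 3): self.ror_13,
            (2, 3): self.ror_23,
        }[tuple(contrast)]

    @property
    def true_omega(self) -> float:
        """True inconsistency on the log-ROR scale.

        omega is the generating direct 2-3 log OR minus the generating
        indirect (via treatment 1) log OR; with multiplicative biases it
        equals ``ln(ror_23) + ln(ror_12) - ln(ror_13)``.
        """
        return math.log(self.ror_23) + math.log(self.ror_12) - math.log(self.ror_13)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_FIELD_NAMES = {f.name for f in fields(ScenarioConfig)}


def _coerce(mapping: dict) -> ScenarioConfig:
    unknown = set(mapping) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return ScenarioConfig(**mapping)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Read a single scenario from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("scenario file must contain a single mapping")
    return _coerce(data)


def expand_grid(mapping: dict) -> list[ScenarioConfig]:
    """Expand list-valued fields into the Cartesian product of scenarios.

    Scalar-valued keys are held fixed; each list-valued key contributes
    one axis.  Generated scenarios get ``name`` suffixes recording the
    varied values unless an explicit name list is given.
    """
    unknown = set(mapping) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    fixed = {k: v for k, v in mapping.items() if not isinstance(v, list)}
    varied = {k: v for k, v in mapping.items() if isinstance(v, list)}
    if not varied:
        return [_coerce(fixed)]
    keys = sorted(varied)
    out = []
    base_name = fixed.pop("name", None)
    for combo in itertools.product(*(varied[k] for k in keys)):
        cell = dict(fixed)
        cell.update(zip(keys, combo))
        tag = "_".join(f"{k}={v}" for k, v in zip(keys, combo))
        cell["name"] = f"{base_name}_{tag}" if base_name else tag
        out.append(_coerce(cell))
    return out


def load_grid(path: str | Path) -> list[ScenarioConfig]:
    """Read a grid file (list-valued fields allowed) and expand it."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("grid file must contain a single mapping")
    return expand_grid(data)


def with_overrides(scenario: ScenarioConfig, **kwargs) -> ScenarioConfig:
    """Return a copy of ``scenario`` with the given fields replaced."""
    return replace(scenario, **kwargs)
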