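"""Frequentist indirect and mixed comparisons, and the inconsistency Z-test.

Sign convention (used package-wide): the effect of a contrast (i, j),
i < j, is the log OR of treatment j relative to treatment i, and the
indirect 2-3 estimate through the common comparator 1 is

    d_23_ind = d_13 - d_12,        Var = Var(d_13) + Var(d_12).

Inconsistency is direct minus indirect, ``omega = d_23 - d_23_ind``.
For a beneficial outcome (OR < 1), omega > 0 means the indirect
comparison over-states the newer treatment's effect relative to the
head-to-head evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pairwise import MetaResult

Z_CRIT = 1.96  # two-sided 5% significance threshold


@dataclass(frozen=True)
class ContrastEstimate:
    """A log OR with variance for one contrast, tagged by provenance."""

    logor: float
    variance: float
    contrast: tuple[int, int]
    provenance: str  # "direct" | "indirect" | "mixed"
    model: str  # "fixed" | "random"

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")

    @property
    def z(self) -> float:
        return self.logor / math.sqrt(self.variance)

    @property
    def significant(self) -> bool:
        """Two-sided Wald test of log OR = 0 at the 5% level."""
        return abs(self.z) > Z_CRIT


@dataclass(frozen=True)
class InconsistencyResult:
    """Bucher inconsistency estimate with its Z statistic."""

    omega: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")

    @property
    def z(self) -> float:
        return self.omega / math.sqrt(self.variance)

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_CRIT


def from_meta(result: MetaResult, provenance: str = "direct") -> ContrastEstimate:
    """Wrap a pooled MetaResult as a ContrastEstimate."""
    if result.contrast is None:
        raise ValueError("MetaResult must carry its contrast")
    return ContrastEstimate(
        result.logor, result.variance, result.contrast, provenance, result.model
    )


def bucher_indirect(
    direct_ab: ContrastEstimate, direct_ac: ContrastEstimate
) -> ContrastEstimate:
    """Adjusted indirect comparison through a shared comparator.

    The two inputs must share their first (comparator) treatment; the
    result is the contrast between their second treatments, with the
    variances summed.
    """
    if direct_ab.contrast[0] != direct_ac.contrast[0]:
        raise ValueError(
            f"no common comparator: {direct_ab.contrast} vs {direct_ac.contrast}"
        )
    if direct_ab.contrast[1] == direct_ac.contrast[1]:
        raise ValueError("inputs compare the same pair of treatments")
    if direct_ab.model != direct_ac.model:
        raise ValueError("inputs must use the same pooling model")
    b, c = direct_ab.contrast[1], direct_ac.contrast[1]
    logor = direct_ac.logor - direct_ab.logor
    variance = direct_ab.variance + direct_ac.variance
    return ContrastEstimate(logor, variance, (b, c), "indirect", direct_ab.model)


def consistency_frequentist_mtc(
    direct_bc: ContrastEstimate, indirect_bc: ContrastEstimate
) -> ContrastEstimate:
    """Pool direct and indirect evidence by inverse-variance weights."""
    if direct_bc.contrast != indirect_bc.contrast:
        raise ValueError("direct and indirect estimates address different contrasts")
    w_d = 1.0 / direct_bc.variance
    w_i = 1.0 / indirect_bc.variance
    logor = (w_d * direct_bc.logor + w_i * indirect_bc.logor) / (w_d + w_i)
    return ContrastEstimate(
        logor, 1.0 / (w_d + w_i), direct_bc.contrast, "mixed", direct_bc.model
    )


def inconsistency_z_test(
    direct_bc: ContrastEstimate, indirect_bc: ContrastEstimate
) -> InconsistencyResult:
    """Z-test of the null that direct and indirect estimates agree."""
    if direct_bc.contrast != indirect_bc.contrast:
        raise ValueError("direct and indirect estimates address different contrasts")
    omega = direct_bc.logor - indirect_bc.logor
    variance = direct_bc.variance + indirect_bc.variance
    return InconsistencyResult(omega, variance)
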