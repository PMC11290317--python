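"""Fixed-effect inverse-variance pooling with Cochran's Q and I².

The effect measure is the raw between-arm mean difference with the usual
two-sample variance ``sd_a²/n_a + sd_b²/n_b`` (the "Mean Difference, IV,
Fixed" model of standard meta-analysis software).  Heterogeneity is
quantified by Cochran's Q and the I² point estimate

    I² = 100 · max(0, (Q − df) / Q),   I² = 0 when Q = 0,

so I² > 0 exactly when Q exceeds its degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial_io import ArmSummary


@dataclass(frozen=True)
class StudyEffect:
    """One study's mean difference and its sampling variance."""

    md: float
    var: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.var) and self.var > 0):
            raise ValueError(f"effect variance must be positive and finite: {self.var}")
        if not math.isfinite(self.md):
            raise ValueError(f"non-finite mean difference: {self.md}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with heterogeneity statistics."""

    pooled_md: float
    pooled_se: float
    q: float
    df: int
    i2: float

    @property
    def positive(self) -> bool:
        """Heterogeneity flag: I² strictly above 0%."""
        return self.i2 > 0.0


def mean_difference_effect(arm_a: ArmSummary, arm_b: ArmSummary) -> StudyEffect:
    """Between-arm mean difference (A − B) with two-sample variance."""
    return StudyEffect(
        md=arm_a.mean - arm_b.mean,
        var=arm_a.variance_of_mean + arm_b.variance_of_mean,
    )


def i_squared(q: float, df: int) -> float:
    """I² point estimate in percent, clamped to [0, 100)."""
    if q < 0:
        raise ValueError(f"negative Q: {q}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if q == 0.0:
        return 0.0
    return 100.0 * max(0.0, (q - df) / q)


def fixed_effect_pool(effects: Sequence[StudyEffect]) -> MetaResult:
    """Pool study effects with inverse-variance fixed-effect weights.

    Weights are w_i = 1/var_i; Q = Σ w_i (md_i − pooled)² on k − 1 degrees
    of freedom.
    """
    if len(effects) < 2:
        raise ValueError(f"need at least 2 studies, got {len(effects)}")
    md = np.array([e.md for e in effects], dtype=float)
    w = np.array([1.0 / e.var for e in effects], dtype=float)
    w_sum = w.sum()
    pooled = float(np.dot(w, md) / w_sum)
    q = float(np.dot(w, (md - pooled) ** 2))
    df = len(effects) - 1
    return MetaResult(
        pooled_md=pooled,
        pooled_se=float(1.0 / np.sqrt(w_sum)),
        q=q,
        df=df,
        i2=i_squared(q, df),
    )
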