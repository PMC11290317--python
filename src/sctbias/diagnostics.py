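"""Diagnostic accuracy of a bias rating judged against the I² test.

Given a confusion table of trial classifications — the I² test as the
reference, the RoB 2 rating as the index "diagnosis" — this module computes
sensitivity, specificity, prevalence, the false omission rate (FOR) with a
95% CI, and the negative likelihood ratio (−LR) with a 95% CI.

Two FOR estimators are provided and reported side by side:

``for_simple``
    the literal definition FN / (FN + TN);
``for_adjusted``
    the prevalence-adjusted predictive-value form
    (1 − Se)·p / (Sp·(1 − p) + (1 − Se)·p), with the prevalence p
    pre-rounded to a fixed number of decimals in percent (default 1), the
    convention of standard diagnostic-test calculators.

With the *unrounded* prevalence the two are algebraically identical; the
rounding makes them differ in the second decimal, which is why both are
surfaced.  The FOR interval is the logit (delta-method) interval on the
corresponding negative predictive value NPV = 1 − FOR; the −LR interval is
the standard log-method interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

# Two-sided 95% standard-normal quantile, to the precision diagnostic
# calculators conventionally use.
Z_95 = 1.959964


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies; "positive" is an I² test positive (I² > 0%),
    "condition present" a high-bias rating."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticSummary:
    """Point estimates and intervals derived from one confusion table."""

    counts: ConfusionCounts
    se: float
    sp: float
    prevalence: float
    for_simple: float
    for_adjusted: float
    for_ci: tuple[float, float]
    neg_lr: float
    neg_lr_ci: tuple[float, float]
    neg_lr_band: str
    z: float = Z_95
    prevalence_rounding: int | None = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        d["for_ci"] = list(self.for_ci)
        d["neg_lr_ci"] = list(self.neg_lr_ci)
        return d


def se_sp_prevalence(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), and prevalence of
    test-positive trials (TP+FN)/total."""
    diseased = c.tp + c.fn
    healthy = c.tn + c.fp
    if diseased < 1 or healthy < 1:
        raise ValueError("empty margin: need at least one positive and one negative")
    return c.tp / diseased, c.tn / healthy, diseased / c.total


def _rounded_prevalence(c: ConfusionCounts, prevalence_rounding: int | None) -> float:
    _, _, prev = se_sp_prevalence(c)
    if prevalence_rounding is None:
        return prev
    return round(100.0 * prev, prevalence_rounding) / 100.0


def for_simple(c: ConfusionCounts) -> float:
    """Literal false omission rate FN / (FN + TN)."""
    if c.fn + c.tn < 1:
        raise ValueError("no negative test results")
    return c.fn / (c.fn + c.tn)


def for_adjusted(c: ConfusionCounts, prevalence_rounding: int | None = 1) -> float:
    """Prevalence-adjusted FOR, (1−Se)·p / (Sp·(1−p) + (1−Se)·p).

    ``prevalence_rounding`` is the number of decimals the prevalence is
    rounded to *in percent* before substitution (None = exact, in which
    case the result equals :func:`for_simple` exactly).
    """
    se, sp, _ = se_sp_prevalence(c)
    p = _rounded_prevalence(c, prevalence_rounding)
    num = (1.0 - se) * p
    den = sp * (1.0 - p) + num
    if den <= 0:
        raise ValueError("degenerate denominator in adjusted FOR")
    return num / den


def for_logit_ci(
    c: ConfusionCounts,
    prevalence_rounding: int | None = 1,
    z: float = Z_95,
) -> tuple[float, float]:
    """Logit (delta-method) 95% CI for the prevalence-adjusted FOR.

    Built on NPV = 1 − FOR:  var(logit NPV) = (1−Sp)/(Sp·(TN+FP)) +
    Se/((1−Se)·(TP+FN)); bounds back-transformed and mapped to FOR.
    """
    se, sp, _ = se_sp_prevalence(c)
    if not (0.0 < se < 1.0 and 0.0 < sp < 1.0):
        raise ValueError("logit interval undefined at boundary Se/Sp")
    npv = 1.0 - for_adjusted(c, prevalence_rounding)
    var = (1.0 - sp) / (sp * (c.tn + c.fp)) + se / ((1.0 - se) * (c.tp + c.fn))
    half = z * math.sqrt(var)
    logit = math.log(npv / (1.0 - npv))
    npv_lo = 1.0 / (1.0 + math.exp(-(logit - half)))
    npv_hi = 1.0 / (1.0 + math.exp(-(logit + half)))
    return 1.0 - npv_hi, 1.0 - npv_lo


def neg_lr(c: ConfusionCounts) -> float:
    """Negative likelihood ratio (1 − Se)/Sp: the likelihood a rating-
    negative (low-bias-rated) trial is actually test-positive relative to
    test-negative."""
    se, sp, _ = se_sp_prevalence(c)
    if sp == 0:
        raise ValueError("specificity is zero; -LR undefined")
    return (1.0 - se) / sp


def neg_lr_ci(c: ConfusionCounts, z: float = Z_95) -> tuple[float, float]:
    """Log-method 95% CI for the negative likelihood ratio:
    var(ln −LR) = Se/((1−Se)·(TP+FN)) + (1−Sp)/(Sp·(TN+FP))."""
    se, sp, _ = se_sp_prevalence(c)
    if not (0.0 < se < 1.0 and 0.0 < sp < 1.0):
        raise ValueError("log interval undefined at boundary Se/Sp")
    point = neg_lr(c)
    var = se / ((1.0 - se) * (c.tp + c.fn)) + (1.0 - sp) / (sp * (c.tn + c.fp))
    half = z * math.sqrt(var)
    return point * math.exp(-half), point * math.exp(half)


# Interpretation bands for -LR, upper-closed at the shared endpoints.
_NEG_LR_BANDS = (
    (0.1, "highly likely"),
    (0.2, "moderately likely"),
    (0.5, "somewhat likely"),
    (1.0, "rarely likely"),
)


def interpret_neg_lr(value: float) -> str:
    """Map a −LR to its interpretation band for the likelihood that a
    rating-negative trial truly has low bias risk; values above 1 mean a
    low-bias rating makes high bias risk *more* likely ("adverse")."""
    if not value > 0:
        raise ValueError(f"-LR must be positive, got {value}")
    for upper, band in _NEG_LR_BANDS:
        if value <= upper:
            return band
    return "adverse"


def summarize(
    c: ConfusionCounts,
    prevalence_rounding: int | None = 1,
    z: float = Z_95,
) -> DiagnosticSummary:
    """Compute the full diagnostic summary for one confusion table."""
    se, sp, prev = se_sp_prevalence(c)
    lr = neg_lr(c)
    return DiagnosticSummary(
        counts=c,
        se=se,
        sp=sp,
        prevalence=prev,
        for_simple=for_simple(c),
        for_adjusted=for_adjusted(c, prevalence_rounding),
        for_ci=for_logit_ci(c, prevalence_rounding, z),
        neg_lr=lr,
        neg_lr_ci=neg_lr_ci(c, z),
        neg_lr_band=interpret_neg_lr(lr),
        z=z,
        prevalence_rounding=prevalence_rounding,
    )
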