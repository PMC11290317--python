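"""Convert reported baseline summaries to the mean(SD) form the test needs.

Trials report baseline variables in four forms: mean(SD), mean(SE),
median(min-max) or median(IQR).  The bias test operates on mean(SD), so

* a reported SE is rescaled, ``SD = SE * sqrt(N)``;
* a median with min-max range is converted with the Hozo estimators;
* a median with IQR is converted with the Wan estimators.

Median-based conversions are approximations (exact only under symmetry),
so converted arms carry ``converted=True`` and are reserved for the
sensitivity analysis; SE-reported arms are direct measurements of the mean
and belong to the main analysis.
"""

from __future__ import annotations

import math

from scipy.stats import norm

from .trial_io import ArmSummary, RawSummary

# Hozo SD rule switches estimator by sample size: the full small-sample
# formula up to 15, range/4 up to 70, range/6 beyond.
HOZO_SMALL_N = 15
HOZO_MEDIUM_N = 70


def se_to_sd(se: float, n: int) -> float:
    """Recover the standard deviation from a reported standard error."""
    if not se > 0:
        raise ValueError(f"non-positive SE: {se}")
    if n < 2:
        raise ValueError(f"arm size must be >= 2, got {n}")
    return se * math.sqrt(n)


def hozo_mean_sd(a: float, m: float, b: float, n: int) -> tuple[float, float]:
    """Estimate mean and SD from a median ``m`` with min ``a`` and max ``b``.

    mean = (a + 2m + b) / 4 for all n; the SD estimator depends on n:
    sqrt(((a - 2m + b)^2 / 4 + (b - a)^2) / 12) for n <= 15, (b - a)/4 for
    n <= 70 and (b - a)/6 otherwise.
    """
    if not (a <= m <= b):
        raise ValueError(f"ordering violated: need {a} <= {m} <= {b}")
    if n < 2:
        raise ValueError(f"arm size must be >= 2, got {n}")
    mean = (a + 2.0 * m + b) / 4.0
    if n <= HOZO_SMALL_N:
        sd = math.sqrt(((a - 2.0 * m + b) ** 2 / 4.0 + (b - a) ** 2) / 12.0)
    elif n <= HOZO_MEDIUM_N:
        sd = (b - a) / 4.0
    else:
        sd = (b - a) / 6.0
    return mean, sd


def wan_mean_sd(q1: float, m: float, q3: float, n: int) -> tuple[float, float]:
    """Estimate mean and SD from a median ``m`` with quartiles ``q1``/``q3``.

    mean = (q1 + m + q3) / 3 and
    SD = (q3 - q1) / (2 * Phi^-1((0.75 n - 0.125) / (n + 0.25))), where
    Phi^-1 is the standard normal quantile.  For large n the denominator
    tends to 2 * 0.6745, i.e. the familiar SD ~= IQR / 1.349.
    """
    if not (q1 <= m <= q3):
        raise ValueError(f"ordering violated: need {q1} <= {m} <= {q3}")
    if n < 2:
        raise ValueError(f"arm size must be >= 2, got {n}")
    if q1 == q3:
        raise ValueError("degenerate IQR (q1 == q3) yields SD = 0")
    mean = (q1 + m + q3) / 3.0
    denom = 2.0 * float(norm.ppf((0.75 * n - 0.125) / (n + 0.25)))
    return mean, (q3 - q1) / denom


def normalize_arm(raw: RawSummary) -> ArmSummary:
    """Dispatch a reported summary to the right converter.

    mean(SD) passes through; mean(SE) is rescaled (still ``converted=False``
    since the mean itself was measured); median-based summaries are
    estimated and flagged ``converted=True``.
    """
    if raw.kind == "mean_sd":
        return ArmSummary(raw.location, raw.spread1, raw.n, converted=False)
    if raw.kind == "mean_se":
        return ArmSummary(
            raw.location, se_to_sd(raw.spread1, raw.n), raw.n, converted=False
        )
    if raw.kind == "median_range":
        mean, sd = hozo_mean_sd(raw.spread1, raw.location, raw.spread2, raw.n)
    elif raw.kind == "median_iqr":
        mean, sd = wan_mean_sd(raw.spread1, raw.location, raw.spread2, raw.n)
    else:  # pragma: no cover - RawSummary already validates kind
        raise ValueError(f"unknown summary kind: {raw.kind!r}")
    return ArmSummary(mean, sd, raw.n, converted=True)
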