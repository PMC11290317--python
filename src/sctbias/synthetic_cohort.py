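"""Synthetic trial cohorts with controllable arm misallocation.

Real appraised trial cohorts are not redistributable, so this module
simulates them: each trial draws two arms of individual baseline values
(age-like, Normal) and reports them as summary statistics.  A *biased*
trial models non-random allocation as a systematic mean shift of one arm
by ``delta`` standard deviations — the baseline imbalance selection bias
produces.  RoB 2 labels are attached truth-consistently, with optional
label noise so rating error can be studied.

Defaults: mean 44 and SD 21 match the first two moments of the uniform
[8, 80] range the comparator trials use, so synthetic trials sit in the
same value range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_io import CohortTable, RawSummary, TrialRecord


@dataclass(frozen=True)
class CohortSimConfig:
    """Simulation settings for one synthetic cohort.

    delta is the systematic arm shift of biased trials, in units of sigma;
    label_noise is the probability that a trial's RoB 2 label contradicts
    its true bias status; domain1_missing the fraction of trials whose
    domain-1 rating is unavailable; median_fraction the fraction of trials
    degraded to median(IQR) reporting to exercise the conversion path.
    """

    n_trials: int = 100
    mu: float = 44.0
    sigma: float = 21.0
    n_per_arm_range: tuple[int, int] = (20, 200)
    delta: float = 0.5
    biased_fraction: float = 0.078
    label_noise: float = 0.0
    domain1_missing: float = 0.28
    median_fraction: float = 0.0
    variable_name: str = "age"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        lo, hi = self.n_per_arm_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid n_per_arm_range: {self.n_per_arm_range}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        for name in ("biased_fraction", "label_noise", "domain1_missing",
                     "median_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion, got {v}")


def _summarize(values: np.ndarray, as_median: bool) -> RawSummary:
    n = len(values)
    if as_median:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return RawSummary("median_iqr", float(med), float(q1), float(q3), n)
    return RawSummary(
        "mean_sd", float(np.mean(values)), float(np.std(values, ddof=1)), None, n
    )


def _label(truth_high: bool, noise: float, rng: np.random.Generator) -> str:
    flip = rng.random() < noise
    high = truth_high != flip
    return "high" if high else "low"


def simulate_trial(
    cfg: CohortSimConfig,
    biased: bool,
    rng: np.random.Generator,
    trial_id: str = "T1",
) -> TrialRecord:
    """Draw one two-arm trial; a biased trial has arm A shifted by
    delta·sigma.  Labels are truth-consistent with probability
    1 − label_noise."""
    lo, hi = cfg.n_per_arm_range
    n_a, n_b = rng.integers(lo, hi + 1, size=2)
    shift = cfg.delta * cfg.sigma if biased else 0.0
    values_a = rng.normal(cfg.mu + shift, cfg.sigma, size=n_a)
    values_b = rng.normal(cfg.mu, cfg.sigma, size=n_b)
    as_median = rng.random() < cfg.median_fraction
    overall = _label(biased, cfg.label_noise, rng)
    if rng.random() < cfg.domain1_missing:
        domain1 = "unknown"
    else:
        domain1 = _label(biased, cfg.label_noise, rng)
    return TrialRecord(
        trial_id=trial_id,
        variable_name=cfg.variable_name,
        arm_a=_summarize(values_a, as_median),
        arm_b=_summarize(values_b, as_median),
        rob2_overall=overall,
        rob2_domain1=domain1,
    )


def simulate_cohort(
    cfg: CohortSimConfig, seed: int | None = 0
) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a cohort plus its ground-truth table.

    ``round(biased_fraction · n_trials)`` trials are biased, their
    positions shuffled.  The truth table (``trial_id``, ``biased``) is
    returned separately so the analysis pipeline never sees it.
    """
    rng = np.random.default_rng(seed)
    n_biased = int(round(cfg.biased_fraction * cfg.n_trials))
    flags = np.zeros(cfg.n_trials, dtype=bool)
    flags[:n_biased] = True
    rng.shuffle(flags)
    width = len(str(cfg.n_trials))
    records, truth = [], []
    for i, biased in enumerate(flags):
        tid = f"T{i + 1:0{width}d}"
        records.append(simulate_trial(cfg, bool(biased), rng, trial_id=tid))
        truth.append({"trial_id": tid, "biased": bool(biased)})
    return CohortTable(records), pd.DataFrame(truth)


def evaluate_against_truth(
    results: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Operating characteristics of the test against simulation truth:
    detection rate among biased trials, false-positive rate among unbiased
    ones.  ``results`` needs columns ``trial_id`` and ``test_positive``."""
    merged = results.merge(truth, on="trial_id", how="inner", validate="1:1")
    if len(merged) != len(results) or len(merged) != len(truth):
        raise ValueError("trial ids in results and truth do not match")
    biased = merged[merged["biased"]]
    clean = merged[~merged["biased"]]
    return {
        "n": len(merged),
        "n_biased": len(biased),
        "detection_rate": float(biased["test_positive"].mean()) if len(biased) else float("nan"),
        "false_positive_rate": float(clean["test_positive"].mean()) if len(clean) else float("nan"),
    }
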