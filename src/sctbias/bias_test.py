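"""The single-trial selection-bias test and its cohort-level driver.

A candidate randomized trial is tested by inserting its baseline-variable
mean difference into a fixed-effect meta-analysis of two confirmed
simulated comparator trials (SCTs).  The SCT pair alone pools to I² = 0;
if the three-study meta-analysis still shows I² = 0% the trial is
test-negative (no selection-bias risk assumed), while any I² > 0% is a
positive result (high selection-bias risk assumed).

The test is exposed as a scikit-learn style detector,
:class:`SelectionBiasI2Test`: ``fit`` prepares (and, in shared-pair mode,
builds) the SCT anchor, ``decision_function`` returns the per-trial I²
in percent and ``predict`` the positive/negative flag.  Module-level
functions (:func:`test_trial`, :func:`run_cohort`) are thin wrappers used
by the CLI.

Classifications against RoB 2 ratings follow the diagnostic convention
with the I² test as the reference standard:

=========  ============  ===========
RoB 2      I² test       class
=========  ============  ===========
high       positive      TP
high       negative      FP
low        negative      TN
low        positive      FN
=========  ============  ===========
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .meta_analysis import StudyEffect, fixed_effect_pool, mean_difference_effect
from .sct_generator import (
    ConfirmedPair,
    SCTConfig,
    build_confirmed_sct_pair,
    sct_effect,
    trial_specific_range,
)
from .summary_conversion import normalize_arm
from .trial_io import ArmSummary, CohortTable, TrialRecord

logger = logging.getLogger(__name__)

ARM_COLUMNS = ["mean_a", "sd_a", "n_a", "mean_b", "sd_b", "n_b"]


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of testing one trial against a confirmed SCT pair."""

    trial_id: str
    i2: float
    positive: bool
    sct_seed: int
    attempts: int


def classify(rob2: str, positive: bool) -> str | None:
    """Confusion-class label for one trial, or None when the rating is
    outside the low/high dichotomy ("some_concerns"/"unknown")."""
    if rob2 == "high":
        return "TP" if positive else "FP"
    if rob2 == "low":
        return "FN" if positive else "TN"
    return None


def tally(labels: Iterable[str | None]):
    """Count TP/FP/TN/FN labels into a ConfusionCounts (None entries are
    skipped); returns None when no trial was classifiable."""
    from .diagnostics import ConfusionCounts

    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for label in labels:
        if label is not None:
            counts[label] += 1
    if sum(counts.values()) == 0:
        return None
    return ConfusionCounts(
        tp=counts["TP"], fp=counts["FP"], tn=counts["TN"], fn=counts["FN"]
    )


def select_arm_pair(arms: Sequence[ArmSummary]) -> tuple[int, int]:
    """For a multi-arm trial, pick the arm pair with the most significant
    baseline difference: the pair maximizing the two-sample z-statistic
    |mean_i − mean_j| / sqrt(sd_i²/n_i + sd_j²/n_j), ties broken by first
    occurrence."""
    if len(arms) < 2:
        raise ValueError("need at least two arms")
    best, best_z = (0, 1), -math.inf
    for i in range(len(arms)):
        for j in range(i + 1, len(arms)):
            z = abs(arms[i].mean - arms[j].mean) / math.sqrt(
                arms[i].variance_of_mean + arms[j].variance_of_mean
            )
            if z > best_z:
                best, best_z = (i, j), z
    return best


def _pair_effects(pair: ConfirmedPair | tuple) -> list[StudyEffect]:
    first, second = pair[0], pair[1]
    return [sct_effect(first), sct_effect(second)]


def _positivity(i2: float, round_display: bool) -> bool:
    """I² > 0% rule; with ``round_display`` the I² is first rounded to
    integer percent, emulating software that displays I² rounded."""
    return (round(i2) if round_display else i2) > 0.0


def test_arms(
    arm_a: ArmSummary,
    arm_b: ArmSummary,
    pair: ConfirmedPair | tuple,
    round_display: bool = False,
) -> float:
    """Pool the two SCT effects with the trial's mean-difference effect and
    return the resulting I² point estimate (percent)."""
    effects = _pair_effects(pair) + [mean_difference_effect(arm_a, arm_b)]
    return fixed_effect_pool(effects).i2


def test_trial(
    trial: TrialRecord,
    pair: ConfirmedPair,
    round_display: bool = False,
    sct_seed: int = -1,
) -> BiasTestResult:
    """Test one trial record (arms normalized on the fly) against a
    confirmed SCT pair."""
    i2 = test_arms(normalize_arm(trial.arm_a), normalize_arm(trial.arm_b), pair)
    attempts = pair.attempts if isinstance(pair, ConfirmedPair) else -1
    return BiasTestResult(
        trial_id=trial.trial_id,
        i2=i2,
        positive=_positivity(i2, round_display),
        sct_seed=sct_seed,
        attempts=attempts,
    )


class SelectionBiasI2Test(BaseEstimator):
    """Selection-bias detector for single randomized trials.

    Each sample is one trial's normalized baseline summary, the six
    columns ``mean_a, sd_a, n_a, mean_b, sd_b, n_b`` (pandas DataFrame or
    array-like in that order).  ``decision_function`` returns the I² point
    estimate (percent) of the trial pooled with two confirmed SCTs;
    ``predict`` returns the boolean positive flag (I² > 0%).

    Parameters
    ----------
    lower, upper, count, block_size : SCT generation settings (value range,
        values per SCT, permuted-block size).
    shared_pair : bool, default False
        Build one confirmed SCT pair at ``fit`` time and reuse it for every
        trial; the default draws a fresh, independently confirmed pair per
        trial, each re-runnable from its recorded seed.
    trial_range : bool, default False
        Derive the SCT value range per trial from mean ± 3·SD of its arms
        instead of the fixed (lower, upper).
    round_display : bool, default False
        Apply the positivity rule to the I² rounded to integer percent
        rather than the exact value.
    max_regenerations : cap on pair regenerations during confirmation.
    random_state : int or None
        Seed for all SCT draws.  Per-trial seeds are derived
        deterministically from it, so results are reproducible and each
        trial's pair can be rebuilt in isolation.
    """

    def __init__(
        self,
        lower: int = 8,
        upper: int = 80,
        count: int = 200,
        block_size: int = 4,
        shared_pair: bool = False,
        trial_range: bool = False,
        round_display: bool = False,
        max_regenerations: int = 1000,
        random_state: int | None = None,
    ):
        self.lower = lower
        self.upper = upper
        self.count = count
        self.block_size = block_size
        self.shared_pair = shared_pair
        self.trial_range = trial_range
        self.round_display = round_display
        self.max_regenerations = max_regenerations
        self.random_state = random_state

    # -- scikit-learn plumbing -------------------------------------------

    def _config(self) -> SCTConfig:
        return SCTConfig(
            lower=self.lower,
            upper=self.upper,
            count=self.count,
            block_size=self.block_size,
            max_regenerations=self.max_regenerations,
        )

    def fit(self, X=None, y=None) -> "SelectionBiasI2Test":
        """Validate parameters and, in shared-pair mode, build the anchor
        pair.  ``X``/``y`` are accepted for pipeline compatibility and
        ignored: the detector learns nothing from the tested trials."""
        cfg = self._config()
        entropy = self.random_state if self.random_state is not None else None
        self.seed_ = int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
        self.config_ = cfg
        if self.shared_pair:
            self.pair_ = build_confirmed_sct_pair(
                cfg, np.random.default_rng(self.seed_)
            )
        else:
            self.pair_ = None
        self.n_features_in_ = len(ARM_COLUMNS)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "config_"):
            raise RuntimeError("this SelectionBiasI2Test instance is not fitted yet")

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in ARM_COLUMNS if c not in X.columns]
            if missing:
                raise ValueError(f"missing arm-summary columns: {missing}")
            return X[ARM_COLUMNS].astype(float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(ARM_COLUMNS):
            raise ValueError(
                f"expected shape (n_trials, {len(ARM_COLUMNS)}), got {arr.shape}"
            )
        return pd.DataFrame(arr, columns=ARM_COLUMNS)

    def _trial_seeds(self, n: int) -> np.ndarray:
        # Fresh SeedSequence each call: seeds depend only on (random_state,
        # row index), so repeated calls on the same cohort are identical.
        return np.random.SeedSequence(self.seed_).generate_state(n) % (2**31)

    # -- the test --------------------------------------------------------

    def test(self, X) -> pd.DataFrame:
        """Run the test on every row; returns a DataFrame with columns
        ``i2``, ``test_positive``, ``sct_seed``, ``attempts``."""
        self._check_fitted()
        frame = self._as_frame(X)
        seeds = self._trial_seeds(len(frame))
        rows = []
        for (_, row), seed in zip(frame.iterrows(), seeds):
            arm_a = ArmSummary(row["mean_a"], row["sd_a"], int(row["n_a"]))
            arm_b = ArmSummary(row["mean_b"], row["sd_b"], int(row["n_b"]))
            if self.pair_ is not None:
                pair, seed = self.pair_, self.seed_
            else:
                cfg = self.config_
                if self.trial_range:
                    cfg = trial_specific_range(arm_a, arm_b, cfg)
                pair = build_confirmed_sct_pair(cfg, np.random.default_rng(int(seed)))
            i2 = test_arms(arm_a, arm_b, pair)
            rows.append(
                {
                    "i2": i2,
                    "test_positive": _positivity(i2, self.round_display),
                    "sct_seed": int(seed),
                    "attempts": pair.attempts,
                }
            )
        return pd.DataFrame(rows, index=frame.index)

    def decision_function(self, X) -> np.ndarray:
        """Per-trial I² point estimate in percent (higher = more evidence
        of baseline imbalance)."""
        return self.test(X)["i2"].to_numpy()

    def predict(self, X) -> np.ndarray:
        """Boolean positivity flags (I² > 0%)."""
        return self.test(X)["test_positive"].to_numpy(dtype=bool)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).predict(X)


@dataclass
class CohortTestReport:
    """Per-trial results plus confusion tallies for one cohort run."""

    results: pd.DataFrame
    confusion_overall: "object"  # ConfusionCounts | None
    confusion_domain1: "object"  # ConfusionCounts | None
    n_tested: int
    n_skipped_converted: int
    n_skipped_variable: int
    n_unclassified_overall: int
    seed: int | None


def run_cohort(
    cohort: CohortTable,
    seed: int | None = 0,
    include_converted: bool = False,
    variable_whitelist: Sequence[str] | None = None,
    shared_pair: bool = False,
    trial_range: bool = False,
    round_display: bool = False,
    cfg: SCTConfig | None = None,
) -> CohortTestReport:
    """Test every eligible trial of a cohort and tally classifications.

    Eligibility: trials whose summaries required a median conversion are
    excluded unless ``include_converted`` (the sensitivity analysis adds
    them); ``variable_whitelist`` restricts to named baseline variables
    (e.g. ``["age"]``).  Two confusion tables are produced — against the
    overall RoB 2 rating (main analysis) and against the domain-1 rating
    restricted to low/high labels (subgroup analysis).
    """
    cfg = cfg or SCTConfig()
    whitelist = set(variable_whitelist) if variable_whitelist else None

    eligible: list[TrialRecord] = []
    n_skip_conv = n_skip_var = 0
    for rec in cohort:
        if whitelist is not None and rec.variable_name not in whitelist:
            n_skip_var += 1
            continue
        if not include_converted and rec.uses_conversion:
            n_skip_conv += 1
            continue
        eligible.append(rec)
    if not eligible:
        raise ValueError("no eligible trials after filtering")

    est = SelectionBiasI2Test(
        lower=cfg.lower,
        upper=cfg.upper,
        count=cfg.count,
        block_size=cfg.block_size,
        shared_pair=shared_pair,
        trial_range=trial_range,
        round_display=round_display,
        max_regenerations=cfg.max_regenerations,
        random_state=seed,
    ).fit()

    arms = [(normalize_arm(r.arm_a), normalize_arm(r.arm_b)) for r in eligible]
    X = pd.DataFrame(
        [[a.mean, a.sd, a.n, b.mean, b.sd, b.n] for a, b in arms],
        columns=ARM_COLUMNS,
    )
    tested = est.test(X)

    rows = []
    n_unclassified = 0
    for rec, (a, b), (_, t) in zip(eligible, arms, tested.iterrows()):
        label = classify(rec.rob2_overall, bool(t["test_positive"]))
        if label is None:
            n_unclassified += 1
        d1 = classify(rec.rob2_domain1, bool(t["test_positive"]))
        rows.append(
            {
                "trial_id": rec.trial_id,
                "variable_name": rec.variable_name,
                "converted": a.converted or b.converted,
                "i2": float(t["i2"]),
                "test_positive": bool(t["test_positive"]),
                "classification": label or "",
                "domain1_classification": d1 or "",
                "sct_seed": int(t["sct_seed"]),
                "attempts": int(t["attempts"]),
            }
        )
    results = pd.DataFrame(rows)
    if n_unclassified:
        logger.info(
            "%d trial(s) outside the low/high overall dichotomy were tested "
            "but not tallied", n_unclassified,
        )
    return CohortTestReport(
        results=results,
        confusion_overall=tally(r["classification"] or None for r in rows),
        confusion_domain1=tally(r["domain1_classification"] or None for r in rows),
        n_tested=len(rows),
        n_skipped_converted=n_skip_conv,
        n_skipped_variable=n_skip_var,
        n_unclassified_overall=n_unclassified,
        seed=seed,
    )
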