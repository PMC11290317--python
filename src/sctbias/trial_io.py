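"""Domain types and CSV I/O for trial baseline-summary cohorts.

A cohort table holds one row per randomized trial: a single baseline
variable (typically age) summarized for one test arm and one control arm,
plus the trial's RoB 2 risk-of-bias ratings (overall and domain 1,
"bias arising from the randomization process").

Cohort CSV column contract (exact order)::

    trial_id, variable_name,
    kind_a, loc_a, spread1_a, spread2_a, n_a,
    kind_b, loc_b, spread1_b, spread2_b, n_b,
    rob2_overall, rob2_domain1

``kind_*`` is one of ``mean_sd``, ``mean_se``, ``median_range``,
``median_iqr``.  ``spread2`` is used only by the median-based kinds (max or
upper quartile) and is left empty otherwise.  Missing values are empty
strings; numbers use a decimal point.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

SUMMARY_KINDS = ("mean_sd", "mean_se", "median_range", "median_iqr")
OVERALL_RATINGS = ("low", "high", "some_concerns")
DOMAIN1_RATINGS = ("low", "high", "some_concerns", "unknown")

COHORT_COLUMNS = [
    "trial_id", "variable_name",
    "kind_a", "loc_a", "spread1_a", "spread2_a", "n_a",
    "kind_b", "loc_b", "spread1_b", "spread2_b", "n_b",
    "rob2_overall", "rob2_domain1",
]


class CohortFormatError(ValueError):
    """Raised for malformed cohort files or rows."""


@dataclass(frozen=True)
class ArmSummary:
    """Mean/SD/N summary of one trial arm's baseline variable.

    ``converted`` marks summaries estimated from a reported median
    (min-max range or IQR); the sensitivity analysis includes or excludes
    such arms as a group.
    """

    mean: float
    sd: float
    n: int
    converted: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"non-finite mean: {self.mean}")
        if not (math.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"non-positive SD: {self.sd}")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"arm size must be an integer >= 2, got {self.n}")
        object.__setattr__(self, "n", int(self.n))

    @property
    def variance_of_mean(self) -> float:
        """Sampling variance of the arm mean, sd^2 / n."""
        return self.sd ** 2 / self.n


@dataclass(frozen=True)
class RawSummary:
    """A baseline summary as reported: mean(SD), mean(SE), median(min-max)
    or median(IQR).  ``location`` is the mean or median; ``spread1``/
    ``spread2`` are (SD, -), (SE, -), (min, max) or (q1, q3) by kind."""

    kind: str
    location: float
    spread1: float
    spread2: float | None
    n: int

    def __post_init__(self) -> None:
        if self.kind not in SUMMARY_KINDS:
            raise ValueError(f"unknown summary kind: {self.kind!r}")
        if not math.isfinite(self.location):
            raise ValueError("non-finite location")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"arm size must be an integer >= 2, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        if self.kind in ("mean_sd", "mean_se"):
            if not (math.isfinite(self.spread1) and self.spread1 > 0):
                label = "SD" if self.kind == "mean_sd" else "SE"
                raise ValueError(f"non-positive {label}: {self.spread1}")
            if self.spread2 is not None:
                raise ValueError(f"{self.kind} takes no second spread value")
        else:
            if self.spread2 is None:
                raise ValueError(f"{self.kind} requires a second spread value")
            lo, hi = self.spread1, self.spread2
            if not (lo <= self.location <= hi):
                raise ValueError(
                    f"ordering violated for {self.kind}: "
                    f"need {lo} <= {self.location} <= {hi}"
                )


@dataclass(frozen=True)
class TrialRecord:
    """One randomized trial: two arms of one baseline variable plus RoB 2
    ratings."""

    trial_id: str
    variable_name: str
    arm_a: RawSummary
    arm_b: RawSummary
    rob2_overall: str
    rob2_domain1: str = "unknown"

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("empty trial_id")
        if self.rob2_overall not in OVERALL_RATINGS:
            raise ValueError(f"unknown rob2_overall rating: {self.rob2_overall!r}")
        if self.rob2_domain1 not in DOMAIN1_RATINGS:
            raise ValueError(f"unknown rob2_domain1 rating: {self.rob2_domain1!r}")

    @property
    def uses_conversion(self) -> bool:
        """True when either arm is median-based and must be converted."""
        return any(
            arm.kind in ("median_range", "median_iqr")
            for arm in (self.arm_a, self.arm_b)
        )


@dataclass
class CohortTable:
    """Ordered collection of trial records with unique ids."""

    records: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.trial_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trial ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> TrialRecord:
        return self.records[i]


def _parse_float(text: str, column: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise CohortFormatError(f"non-numeric {column}: {text!r}") from exc


def _parse_optional_float(text: str, column: str) -> float | None:
    return None if text == "" else _parse_float(text, column)


def _parse_int(text: str, column: str) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise CohortFormatError(f"non-integer {column}: {text!r}") from exc


def _parse_arm(row: dict[str, str], suffix: str) -> RawSummary:
    try:
        return RawSummary(
            kind=row[f"kind_{suffix}"].strip(),
            location=_parse_float(row[f"loc_{suffix}"], f"loc_{suffix}"),
            spread1=_parse_float(row[f"spread1_{suffix}"], f"spread1_{suffix}"),
            spread2=_parse_optional_float(
                row[f"spread2_{suffix}"], f"spread2_{suffix}"
            ),
            n=_parse_int(row[f"n_{suffix}"], f"n_{suffix}"),
        )
    except ValueError as exc:
        raise CohortFormatError(str(exc)) from exc


def parse_record(row: dict[str, str]) -> TrialRecord:
    """Build a validated :class:`TrialRecord` from one CSV row dict."""
    domain1 = row.get("rob2_domain1", "").strip() or "unknown"
    try:
        return TrialRecord(
            trial_id=row["trial_id"].strip(),
            variable_name=row["variable_name"].strip(),
            arm_a=_parse_arm(row, "a"),
            arm_b=_parse_arm(row, "b"),
            rob2_overall=row["rob2_overall"].strip(),
            rob2_domain1=domain1,
        )
    except CohortFormatError:
        raise
    except ValueError as exc:
        raise CohortFormatError(str(exc)) from exc


def read_cohort(path: str | Path, strict: bool = True) -> CohortTable:
    """Read and validate a cohort CSV.

    In strict mode any malformed row aborts with :class:`CohortFormatError`;
    otherwise malformed rows are skipped with a logged reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames:
            raise CohortFormatError("empty cohort")
        if list(reader.fieldnames) != COHORT_COLUMNS:
            raise CohortFormatError(
                f"unexpected header {reader.fieldnames}; expected {COHORT_COLUMNS}"
            )
        records: list[TrialRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(parse_record(row))
            except CohortFormatError as exc:
                if strict:
                    raise CohortFormatError(f"line {lineno}: {exc}") from exc
                logger.warning("skipping line %d: %s", lineno, exc)
    if not records:
        raise CohortFormatError("empty cohort")
    return CohortTable(records)


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return format(float(value), ".17g")


def _arm_fields(arm: RawSummary) -> list[str]:
    return [arm.kind, _fmt(arm.location), _fmt(arm.spread1),
            _fmt(arm.spread2), str(arm.n)]


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; ``read_cohort`` of the output round-trips."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in cohort:
            domain1 = "" if rec.rob2_domain1 == "unknown" else rec.rob2_domain1
            writer.writerow(
                [rec.trial_id, rec.variable_name,
                 *_arm_fields(rec.arm_a), *_arm_fields(rec.arm_b),
                 rec.rob2_overall, domain1]
            )


def write_results(results, path: str | Path, diagnostics: dict | None = None) -> None:
    """Write per-trial test results as CSV and, optionally, a diagnostics
    report as JSON next to it (same stem, ``.json`` suffix).

    ``results`` is an iterable of mappings (or a pandas DataFrame) with at
    least ``trial_id``, ``i2``, ``test_positive``, ``classification``.
    Numeric fields are written with full precision so that reading the file
    back reproduces them beyond 12 significant digits.
    """
    path = Path(path)
    if hasattr(results, "to_dict"):  # pandas DataFrame
        rows: Sequence[dict] = results.to_dict("records")
    else:
        rows = list(results)
    if not rows:
        raise ValueError("no results to write")
    columns = list(rows[0].keys())
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            out = []
            for col in columns:
                val = row[col]
                if val is None or (isinstance(val, float) and math.isnan(val)):
                    out.append("")
                elif isinstance(val, float):
                    out.append(_fmt(val))
                else:
                    out.append(str(val))
            writer.writerow(out)
    if diagnostics is not None:
        path.with_suffix(".json").write_text(json.dumps(diagnostics, indent=2))
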