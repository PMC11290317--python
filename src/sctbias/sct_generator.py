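"""Simulated comparator trials (SCTs).

An SCT is an artificial two-arm "trial" built to be perfectly homogeneous:
integers are drawn uniformly (with replacement) from a fixed range, sorted
ascending, and dealt into two balanced arms by a permuted-block allocation
sequence (block size 4).  Because neighbouring order statistics are nearly
equal and every block sends two values to each arm, the two arm means are
almost identical; a fixed-effect meta-analysis of two such SCTs therefore
pools to I² = 0, giving a homogeneous anchor against which a real trial's
baseline imbalance can be measured.

Defaults mirror the reference construction: values in [8, 80] (years of
age), 200 values per SCT, 100 per arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .meta_analysis import fixed_effect_pool, mean_difference_effect
from .trial_io import ArmSummary

ARM_LABELS = ("A", "B")


@dataclass(frozen=True)
class SCTConfig:
    """Generation settings for one SCT.

    lower/upper: inclusive integer bounds of the value range.
    count: total values per SCT (split evenly over the two arms).
    block_size: permuted-block size for the allocation sequence.
    max_regenerations: cap on pair regenerations while confirming I² = 0.
    """

    lower: int = 8
    upper: int = 80
    count: int = 200
    block_size: int = 4
    max_regenerations: int = 1000

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper}]")
        if self.block_size < 2 or self.block_size % 2:
            raise ValueError(f"block size must be a positive even integer: {self.block_size}")
        if self.count <= 0 or self.count % self.block_size:
            raise ValueError(
                f"count must be a positive multiple of block_size, got {self.count}"
            )
        if self.max_regenerations < 1:
            raise ValueError("max_regenerations must be >= 1")


@dataclass(frozen=True)
class AllocationSequence:
    """Permuted-block sequence over arm labels A/B."""

    labels: tuple[str, ...]
    block_size: int

    def __post_init__(self) -> None:
        k = self.block_size
        if len(self.labels) % k:
            raise ValueError("sequence length not divisible by block size")
        for start in range(0, len(self.labels), k):
            block = self.labels[start:start + k]
            if block.count("A") != k // 2:
                raise ValueError(f"unbalanced block at position {start}: {block}")


@dataclass(frozen=True)
class SCT:
    """One simulated comparator trial: the sorted raw values, their
    allocation, and the resulting per-arm summaries."""

    values: tuple[int, ...]
    allocation: AllocationSequence
    arm_a: ArmSummary
    arm_b: ArmSummary


class ConfirmedPair(NamedTuple):
    """Pair of independently generated SCTs whose two-study fixed-effect
    meta-analysis was confirmed to give I² = 0, plus the attempts used."""

    first: SCT
    second: SCT
    attempts: int


def block_randomize(
    length: int, block_size: int, rng: np.random.Generator
) -> AllocationSequence:
    """Draw a permuted-block A/B allocation sequence.

    Each consecutive block is an independent uniform draw from the balanced
    arrangements of ``block_size/2`` A's and B's.
    """
    if length <= 0 or length % block_size:
        raise ValueError(f"length {length} not divisible by block size {block_size}")
    half = block_size // 2
    base = np.array(["A"] * half + ["B"] * half)
    labels: list[str] = []
    for _ in range(length // block_size):
        labels.extend(rng.permutation(base))
    return AllocationSequence(tuple(labels), block_size)


def sample_sorted_values(cfg: SCTConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``cfg.count`` integers uniformly with replacement from
    [lower, upper] and return them sorted ascending."""
    values = rng.integers(cfg.lower, cfg.upper + 1, size=cfg.count)
    return np.sort(values)


def _arm_summary(values: np.ndarray) -> ArmSummary:
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate SCT arm: zero standard deviation")
    return ArmSummary(mean=float(np.mean(values)), sd=sd, n=len(values))


def build_sct(cfg: SCTConfig, rng: np.random.Generator) -> SCT:
    """Generate one SCT: fresh allocation sequence and fresh sorted values,
    paired positionally, with per-arm mean and sample SD (n − 1)."""
    allocation = block_randomize(cfg.count, cfg.block_size, rng)
    values = sample_sorted_values(cfg, rng)
    labels = np.array(allocation.labels)
    return SCT(
        values=tuple(int(v) for v in values),
        allocation=allocation,
        arm_a=_arm_summary(values[labels == "A"]),
        arm_b=_arm_summary(values[labels == "B"]),
    )


def sct_effect(sct: SCT):
    """Mean-difference effect (arm A − arm B) of one SCT."""
    return mean_difference_effect(sct.arm_a, sct.arm_b)


def build_confirmed_sct_pair(
    cfg: SCTConfig, rng: np.random.Generator
) -> ConfirmedPair:
    """Generate independent SCT pairs until their two-study fixed-effect
    meta-analysis gives I² = 0, regenerating the whole pair otherwise.

    The sorted-block construction makes confirmation overwhelmingly likely
    on the first attempt; the loop is a guard, capped at
    ``cfg.max_regenerations``.
    """
    for attempt in range(1, cfg.max_regenerations + 1):
        first = build_sct(cfg, rng)
        second = build_sct(cfg, rng)
        pooled = fixed_effect_pool([sct_effect(first), sct_effect(second)])
        if pooled.i2 == 0.0:
            return ConfirmedPair(first, second, attempt)
    raise RuntimeError(
        f"no confirmed SCT pair within {cfg.max_regenerations} regenerations"
    )


def trial_specific_range(
    arm_a: ArmSummary, arm_b: ArmSummary, cfg: SCTConfig | None = None
) -> SCTConfig:
    """Derive SCT bounds from a tested trial: mean ± 3·SD over both arms,
    rounded outward to integers.  Returns a config based on ``cfg`` (or the
    defaults) with the bounds replaced."""
    base = cfg or SCTConfig()
    lower = math.floor(min(arm_a.mean - 3 * arm_a.sd, arm_b.mean - 3 * arm_b.sd))
    upper = math.ceil(max(arm_a.mean + 3 * arm_a.sd, arm_b.mean + 3 * arm_b.sd))
    return replace(base, lower=lower, upper=upper)


def sct_to_rows(sct: SCT) -> list[tuple[str, int]]:
    """Two-column (allocation label, value) rows mirroring the worksheet
    layout in which SCTs are conventionally entered."""
    return list(zip(sct.allocation.labels, sct.values))
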