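"""Amplicon-panel coverage QC against per-base depth thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from col4dx.config import QcThresholds

__all__ = [
    "TargetRegionSet",
    "DepthTrack",
    "CoverageSummary",
    "coverage_summary",
    "QcRuleResult",
    "QcVerdict",
    "qc_verdict",
]


@dataclass(frozen=True)
class TargetRegionSet:
    """Named target regions with their lengths in bases."""

    regions: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for region_id, length in self.regions:
            if length <= 0:
                raise ValueError(f"non-positive length for region {region_id!r}")

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.regions)


@dataclass(frozen=True)
class DepthTrack:
    """Per-base integer depths, optionally aligned to a TargetRegionSet."""

    depths: np.ndarray
    targets: TargetRegionSet | None = None

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=np.int64)
        if depths.ndim != 1:
            raise ValueError("depth track must be one-dimensional")
        if depths.size and depths.min() < 0:
            raise ValueError("depths must be non-negative")
        if self.targets is not None and depths.size != self.targets.total_bp:
            raise ValueError(
                f"track length {depths.size} does not match target size {self.targets.total_bp}"
            )
        object.__setattr__(self, "depths", depths)

    def __len__(self) -> int:
        return self.depths.size


@dataclass(frozen=True)
class CoverageSummary:
    mean_depth: float
    fraction_at_or_above: Mapping[int, float]
    n_bases: int

    def to_dict(self) -> dict:
        return {
            "mean_depth": self.mean_depth,
            "fraction_at_or_above": {str(k): v for k, v in self.fraction_at_or_above.items()},
            "n_bases": self.n_bases,
        }


def coverage_summary(
    track: DepthTrack, thresholds: Sequence[int] = (25, 50, 100)
) -> CoverageSummary:
    """Mean depth and, per threshold t, the fraction of bases with depth >= t."""
    depths = track.depths
    if depths.size == 0:
        raise ValueError("empty depth track")
    fractions = {int(t): float(np.mean(depths >= t)) for t in thresholds}
    return CoverageSummary(float(depths.mean()), fractions, int(depths.size))


@dataclass(frozen=True)
class QcRuleResult:
    rule: str
    passed: bool
    observed: float
    required: float

    def to_dict(self) -> dict:
        return vars(self)


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    rules: tuple[QcRuleResult, ...]

    def to_dict(self) -> dict:
        return {"passed": self.passed, "rules": [r.to_dict() for r in self.rules]}


def qc_verdict(summary: CoverageSummary, config: QcThresholds = QcThresholds()) -> QcVerdict:
    """Evaluate each coverage rule separately and combine.

    Fraction rules are strict ("more than") by default: a fraction
    exactly at its threshold fails.  The mean-depth rule is inclusive.
    """
    rules: list[QcRuleResult] = []
    for depth, min_fraction in sorted(config.min_fraction_at.items(), reverse=True):
        if depth not in summary.fraction_at_or_above:
            raise ValueError(f"summary lacks the {depth}x fraction needed by QC config")
        observed = summary.fraction_at_or_above[depth]
        ok = observed > min_fraction if config.strict else observed >= min_fraction
        rules.append(QcRuleResult(f"fraction_at_{depth}x", ok, observed, min_fraction))
    rules.append(
        QcRuleResult(
            "mean_depth",
            summary.mean_depth >= config.min_mean_depth,
            summary.mean_depth,
            config.min_mean_depth,
        )
    )
    return QcVerdict(all(r.passed for r in rules), tuple(rules))
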