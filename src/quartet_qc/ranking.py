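"""Percentile ranking of batch total scores against historical batches.

A submitted batch's total score is ranked among the total scores of
historical batches for the same omics type; the percentile (midrank tie
convention) maps to one of four performance categories:

* great — top 20 % (percentile >= 80)
* good  — between the top 20 % and the median (50 <= percentile < 80)
* fair  — between the median and the bottom 20 % (20 <= percentile < 50)
* bad   — bottom 20 % (percentile < 20)

Boundary inclusivity is this package's documented convention; at least
five historical scores are required for the quartile categories to mean
anything.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

__all__ = [
    "MIN_HISTORICAL",
    "DEFAULT_THRESHOLDS",
    "HistoricalScores",
    "PerformanceCategory",
    "percentile_rank",
    "categorize",
    "load_historical",
    "default_historical",
]

MIN_HISTORICAL = 5
#: Percentile cut points for (great, good, fair); below the last is bad.
DEFAULT_THRESHOLDS: tuple[float, float, float] = (80.0, 50.0, 20.0)


class PerformanceCategory(str, enum.Enum):
    GREAT = "great"
    GOOD = "good"
    FAIR = "fair"
    BAD = "bad"


@dataclass
class HistoricalScores:
    """Total scores of historical batches for one omics type.

    ``metrics`` optionally carries per-metric historical distributions
    (needed for the proteomics scaling).
    """

    omics: str
    scores: list[float]
    version: str = "unversioned"
    metrics: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(math.isfinite(s) for s in self.scores):
            raise ValueError("historical scores must all be finite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "omics": self.omics,
            "version": self.version,
            "scores": self.scores,
        }
        if self.metrics:
            payload["metrics"] = self.metrics
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HistoricalScores":
        raw = json.loads(Path(path).read_text())
        return cls(
            omics=raw["omics"],
            scores=[float(s) for s in raw["scores"]],
            version=raw.get("version", "unversioned"),
            metrics={k: list(map(float, v)) for k, v in raw.get("metrics", {}).items()},
        )


load_historical = HistoricalScores.from_json


def default_historical(omics: str) -> HistoricalScores:
    """Load the simulator-derived historical scores shipped with the package."""
    ref = resources.files("quartet_qc").joinpath(f"data/historical/{omics}.json")
    with resources.as_file(ref) as path:
        return HistoricalScores.from_json(path)


def percentile_rank(score: float, historical: HistoricalScores) -> float:
    """Midrank percentile of a score among historical batch scores.

    percentile = 100 * (#{h < score} + 0.5 * #{h == score}) / N.
    """
    n = len(historical.scores)
    if n < MIN_HISTORICAL:
        raise ValueError(
            f"need >= {MIN_HISTORICAL} historical scores to rank (got {n}); "
            "supply more historical batches"
        )
    below = sum(1 for h in historical.scores if h < score)
    ties = sum(1 for h in historical.scores if h == score)
    return 100.0 * (below + 0.5 * ties) / n


def categorize(
    percentile: float,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> PerformanceCategory:
    """Map a percentile in [0, 100] to a performance category."""
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    great, good, fair = thresholds
    if percentile >= great:
        return PerformanceCategory.GREAT
    if percentile >= good:
        return PerformanceCategory.GOOD
    if percentile >= fair:
        return PerformanceCategory.FAIR
    return PerformanceCategory.BAD
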