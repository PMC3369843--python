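"""Calling allelic imbalance from empirical assay data.

Two evidence types are supported, mirroring the common assay designs:

* **array-style marker records** — per transcribed heterozygous marker, raw
  two-channel intensities and an allelic-imbalance index (the absolute
  difference of normalised allelic expression).  An individual is called AI
  when the mean index over its informative markers exceeds a threshold
  (default 0.1).
* **count-style marker records** — per-marker RNA-seq allele counts tested
  against an expected reference fraction (after mapping-bias correction) with
  an exact two-sided binomial test.  An individual is AI when any marker is
  significant at the per-marker alpha (default 0.01, uncorrected).

Individuals with no usable markers are a distinct third state,
``undetermined``, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "ArrayMarkerRecord",
    "CountMarkerRecord",
    "AICallConfig",
    "call_ai_from_array",
    "marker_count_test",
    "call_ai_from_counts",
    "call_ai_table",
]

AI = "AI"
NON_AI = "non-AI"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ArrayMarkerRecord:
    """One array marker: raw channel intensities and the per-marker AI index."""

    marker: str
    x_raw: float
    y_raw: float
    het: bool
    delta_het_ratio: float

    def __post_init__(self) -> None:
        if self.x_raw < 0 or self.y_raw < 0:
            raise ValueError("raw intensities must be non-negative")
        if abs(self.delta_het_ratio) > 1:
            raise ValueError("|delta_het_ratio| cannot exceed 1")

    def intensity(self, transform: str = "identity") -> float:
        """Combined intensity statistic of the marker.

        The conventional informativeness rule is written against the combined
        raw intensity; ``transform='log'`` applies a natural log first for
        data already reported on that scale.
        """
        total = self.x_raw + self.y_raw
        if transform == "log":
            return math.log(total) if total > 0 else float("-inf")
        return total


@dataclass(frozen=True)
class CountMarkerRecord:
    """One RNA-seq marker: reference/alternate read counts and the null ratio."""

    marker: str
    ref_count: int
    alt_count: int
    null_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if not (0.0 < self.null_ratio < 1.0):
            raise ValueError("null_ratio must be inside (0, 1)")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class AICallConfig:
    ai_index_threshold: float = 0.1
    intensity_min: float = 1000.0
    marker_alpha: float = 0.01
    marker_policy: str = "all_informative"  # or "significant_only"
    intensity_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.ai_index_threshold <= 0 or self.intensity_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.marker_alpha < 1.0):
            raise ValueError("marker_alpha must be inside (0, 1)")
        if self.marker_policy not in ("all_informative", "significant_only"):
            raise ValueError("unknown marker_policy")


def call_ai_from_array(records: Iterable[ArrayMarkerRecord],
                       config: AICallConfig = AICallConfig()
                       ) -> tuple[str, float | None]:
    """AI call for one individual from array marker records.

    Heterozygous markers are informative; under the ``significant_only``
    policy they must additionally clear the combined-intensity threshold.
    The call compares the mean absolute AI index of the selected markers with
    ``ai_index_threshold``.  Returns (status, mean index or None).
    """
    selected = []
    for rec in records:
        if not rec.het:
            continue
        if (config.marker_policy == "significant_only"
                and rec.intensity(config.intensity_transform)
                <= config.intensity_min):
            continue
        selected.append(abs(rec.delta_het_ratio))
    if not selected:
        return UNDETERMINED, None
    mean_index = float(np.mean(selected))
    status = AI if mean_index > config.ai_index_threshold else NON_AI
    return status, mean_index


def marker_count_test(record: CountMarkerRecord) -> float:
    """Exact two-sided binomial p for one marker's allele counts.

    Tests the reference count out of the total against ``null_ratio`` with
    the point-probability two-sided rule.
    """
    if record.total == 0:
        raise ValueError("marker has zero total reads")
    return float(binomtest(record.ref_count, record.total,
                           record.null_ratio).pvalue)


def call_ai_from_counts(records: Iterable[CountMarkerRecord],
                        config: AICallConfig = AICallConfig()) -> str:
    """AI call for one individual: any marker significant at ``marker_alpha``."""
    usable = [r for r in records if r.total > 0]
    if not usable:
        return UNDETERMINED
    if any(marker_count_test(r) < config.marker_alpha for r in usable):
        return AI
    return NON_AI


def call_ai_table(path, mode: str, config: AICallConfig = AICallConfig()
                  ) -> pd.DataFrame:
    """Call AI for every individual of a marker-record TSV.

    ``mode='array'`` expects columns individual, marker, X_raw, Y_raw, het,
    delta_het_ratio; ``mode='counts'`` expects individual, marker, ref_count,
    alt_count and optionally null_ratio.  Returns a DataFrame with columns
    individual_id, ai (0/1, empty for undetermined) and status.
    """
    df = pd.read_csv(path, sep="\t")
    rows = []
    for ind, grp in df.groupby("individual", sort=True):
        if mode == "array":
            recs = [
                ArrayMarkerRecord(str(r.marker), float(r.X_raw), float(r.Y_raw),
                                  bool(r.het), float(r.delta_het_ratio))
                for r in grp.itertuples()
            ]
            status, _ = call_ai_from_array(recs, config)
        elif mode == "counts":
            recs = [
                CountMarkerRecord(
                    str(r.marker), int(r.ref_count), int(r.alt_count),
                    float(getattr(r, "null_ratio", 0.5)))
                for r in grp.itertuples()
            ]
            status = call_ai_from_counts(recs, config)
        else:
            raise ValueError("mode must be 'array' or 'counts'")
        rows.append({
            "individual_id": ind,
            "ai": {AI: 1, NON_AI: 0}.get(status, pd.NA),
            "status": status,
        })
    return pd.DataFrame(rows)
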