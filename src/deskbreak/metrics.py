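"""Compliance, response-latency distribution and process-measure summaries.

Compliance is the percentage of triggered prompts answered by an
ambulatory-bout onset within the compliance window (15 min, inclusive);
unanswered prompts stay in the denominator.  The latency distribution is
binned right-closed — (0, 5], (5, 10], (10, 15] minutes — so the three bins
union exactly to the complied-with prompts; everything slower or unanswered
falls in the trailing ``slow_or_none`` bin.

Summaries are reported two ways and never conflated: pooled ratios (summed
numerators over summed denominators across the cohort) and per-participant
distributions (mean, sample SD, median, 25th/75th percentile with linear
interpolation).  Internal arithmetic is full precision; rounding to one
decimal happens only at report emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import AlgorithmConfig
from .prompts import PromptResponse

__all__ = [
    "ParticipantMetrics",
    "compliance",
    "latency_histogram",
    "pooled_summary",
    "minutes_to_hours",
]


@dataclass(frozen=True)
class ParticipantMetrics:
    """Per-participant process measures."""

    participant: str
    tracking_days: int
    valid_days: int
    adherence_pct: float
    quality_pct: float | None
    n_prompts: int
    n_compliant: int
    compliance_pct: float | None
    latency_histogram: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_compliant > self.n_prompts:
            raise ValueError("n_compliant cannot exceed n_prompts")
        if self.latency_histogram and sum(self.latency_histogram.values()) != self.n_prompts:
            raise ValueError("latency histogram must sum to n_prompts")


def compliance(
    responses: Sequence[PromptResponse], config: AlgorithmConfig
) -> float | None:
    """Percent of all prompts answered within the compliance window.

    Latency exactly equal to the window (15.0 min) is complied with
    ("15 minutes or less").  Returns ``None`` when no prompts were triggered.
    """
    if not responses:
        return None
    n_compliant = sum(
        1
        for r in responses
        if r.latency_minutes is not None
        and r.latency_minutes <= config.compliance_latency_minutes
    )
    return 100.0 * n_compliant / len(responses)


def _bin_labels(config: AlgorithmConfig) -> list[str]:
    edges = config.latency_bin_edges_minutes
    labels = []
    lo = 0.0
    for hi in edges:
        labels.append(f"{lo:g}-{hi:g}min")
        lo = hi
    labels.append("slow_or_none")
    return labels


def latency_histogram(
    responses: Sequence[PromptResponse], config: AlgorithmConfig
) -> dict[str, dict[str, float]]:
    """Right-closed latency bins with counts and percent of all prompts.

    Returns ``{bin_label: {"count": int, "pct": float}}``; percentages are
    rounded to one decimal (presentation convention).  Prompts slower than
    the last edge or never answered fall in ``slow_or_none``, so the counts
    always partition the prompt total.
    """
    edges = config.latency_bin_edges_minutes
    labels = _bin_labels(config)
    counts = {label: 0 for label in labels}
    for r in responses:
        lat = r.latency_minutes
        if lat is None or lat > edges[-1]:
            counts["slow_or_none"] += 1
            continue
        lo = 0.0
        for label, hi in zip(labels, edges):
            if lo < lat <= hi or (lat == 0.0 and lo == 0.0):
                counts[label] += 1
                break
            lo = hi
    total = len(responses)
    return {
        label: {
            "count": counts[label],
            "pct": round(100.0 * counts[label] / total, 1) if total else math.nan,
        }
        for label in labels
    }


def pooled_summary(
    all_metrics: Sequence[ParticipantMetrics],
) -> dict[str, dict[str, float]]:
    """Cohort summary: per-participant distributions plus pooled ratios.

    Pooled quality = sum(valid days)/sum(tracking days); pooled compliance =
    sum(compliant)/sum(prompts).  These generally differ from the mean of the
    per-participant ratios, so both are reported.  With a single participant
    the sample SD is undefined and reported as 0 with ``sd_defined = 0``.
    """
    if not all_metrics:
        raise ValueError("pooled_summary needs at least one participant")

    def describe(values: Sequence[float]) -> dict[str, float]:
        arr = np.asarray([v for v in values if v is not None], dtype=float)
        if arr.size == 0:
            return {"mean": math.nan, "sd": math.nan, "median": math.nan,
                    "p25": math.nan, "p75": math.nan, "n": 0, "sd_defined": 0}
        sd_defined = int(arr.size > 1)
        return {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if sd_defined else 0.0,
            "median": float(np.median(arr)),
            "p25": float(np.percentile(arr, 25)),
            "p75": float(np.percentile(arr, 75)),
            "n": int(arr.size),
            "sd_defined": sd_defined,
        }

    out: dict[str, dict[str, float]] = {
        "tracking_days": describe([m.tracking_days for m in all_metrics]),
        "valid_days": describe([m.valid_days for m in all_metrics]),
        "adherence_pct": describe([m.adherence_pct for m in all_metrics]),
        "quality_pct": describe([m.quality_pct for m in all_metrics]),
        "compliance_pct": describe([m.compliance_pct for m in all_metrics]),
        "n_prompts": describe([m.n_prompts for m in all_metrics]),
    }
    total_tracking = sum(m.tracking_days for m in all_metrics)
    total_valid = sum(m.valid_days for m in all_metrics)
    total_prompts = sum(m.n_prompts for m in all_metrics)
    total_compliant = sum(m.n_compliant for m in all_metrics)
    out["pooled"] = {
        "tracking_days": total_tracking,
        "valid_days": total_valid,
        "quality_pct": 100.0 * total_valid / total_tracking if total_tracking else math.nan,
        "n_prompts": total_prompts,
        "n_compliant": total_compliant,
        "compliance_pct": 100.0 * total_compliant / total_prompts if total_prompts else math.nan,
    }
    return out


def minutes_to_hours(minutes: float, ndigits: int = 1) -> float:
    """Convert minutes to hours, rounded for presentation (414.2 min -> 6.9 h)."""
    return round(minutes / 60.0, ndigits)
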