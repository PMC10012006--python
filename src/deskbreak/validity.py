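"""Tracking-validity classification, valid-day rules, adherence and quality.

The wrist sensor streams a count every 15 s whenever tracking is on; a
dropped Bluetooth link or removed band shows up as runs of zero counts.  A
maximal run of zeros spanning at least ``invalid_run_epochs`` epochs (default
40, i.e. 10 min of no data) is classified as *invalid tracking*; every other
epoch is valid.  A tracking day with strictly more than 3 h of valid time and
strictly less than 3 h of invalid time is a *valid tracking day*.

Two participant-level process measures follow:

* adherence   = 100 x tracking days / possible tracking days (default 30)
* quality of tracking = 100 x valid tracking days / tracking days
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._runs import maximal_runs
from .config import AlgorithmConfig
from .streams import EpochSeries

__all__ = [
    "ValidityMask",
    "DayValidity",
    "classify_epoch_validity",
    "classify_day",
    "adherence",
    "quality_of_tracking",
]


@dataclass(frozen=True)
class ValidityMask:
    """Per-epoch valid/invalid labels for one tracking day.

    ``valid`` is a boolean array aligned to the day's epoch grid
    (True = valid tracking).  Minute totals are derived with epoch-resolution
    arithmetic; nothing is rounded until report emission.
    """

    valid: np.ndarray
    epoch_seconds: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    def __len__(self) -> int:
        return int(self.valid.size)

    @property
    def valid_minutes(self) -> float:
        return int(self.valid.sum()) * self.epoch_seconds / 60.0

    @property
    def invalid_minutes(self) -> float:
        return int((~self.valid).sum()) * self.epoch_seconds / 60.0


@dataclass(frozen=True)
class DayValidity:
    """Day-level validity verdict and minute totals."""

    participant: str
    day: int
    tracking_day: bool
    is_valid_day: bool
    valid_minutes: float
    invalid_minutes: float

    def __post_init__(self) -> None:
        if self.is_valid_day and not self.tracking_day:
            raise ValueError("a valid day must be a tracking day")


def classify_epoch_validity(
    series: EpochSeries, config: AlgorithmConfig
) -> ValidityMask:
    """Label every epoch of ``series`` valid or invalid.

    Every maximal run of zero-count epochs of length >= ``invalid_run_epochs``
    is invalid; all remaining epochs (including shorter zero runs) are valid.
    Runs touching the day boundaries are treated like interior runs.
    """
    counts = series.counts
    if (counts < 0).any():
        raise ValueError("activity counts must be non-negative")
    valid = np.ones(counts.size, dtype=bool)
    for start, end in maximal_runs(counts == 0):
        if end - start >= config.invalid_run_epochs:
            valid[start:end] = False
    return ValidityMask(valid=valid, epoch_seconds=config.epoch_seconds)


def classify_day(
    mask: ValidityMask,
    config: AlgorithmConfig,
    participant: str = "",
    day: int = 0,
) -> DayValidity:
    """Apply the valid-tracking-day rule to one day's mask.

    Both bounds are strict: valid time must exceed
    ``valid_day_min_valid_minutes`` ("over 3 hours") and invalid time must
    stay below ``valid_day_max_invalid_minutes`` ("less than 3 hours").
    """
    vm, im = mask.valid_minutes, mask.invalid_minutes
    is_valid = (
        vm > config.valid_day_min_valid_minutes
        and im < config.valid_day_max_invalid_minutes
    )
    return DayValidity(
        participant=participant,
        day=day,
        tracking_day=True,
        is_valid_day=is_valid,
        valid_minutes=vm,
        invalid_minutes=im,
    )


def adherence(
    participant_days: Iterable[DayValidity], config: AlgorithmConfig
) -> float:
    """Percent of the possible intervention workdays that were tracked."""
    if config.possible_tracking_days == 0:
        raise ValueError("possible_tracking_days must be nonzero for adherence")
    n_tracking = sum(1 for d in participant_days if d.tracking_day)
    return 100.0 * n_tracking / config.possible_tracking_days


def quality_of_tracking(participant_days: Sequence[DayValidity]) -> float | None:
    """Percent of tracking days that were valid; ``None`` with no tracking days."""
    n_tracking = sum(1 for d in participant_days if d.tracking_day)
    if n_tracking == 0:
        return None
    n_valid = sum(1 for d in participant_days if d.is_valid_day)
    return 100.0 * n_valid / n_tracking
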