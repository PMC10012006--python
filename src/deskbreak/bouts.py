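"""Stationary / ambulatory bout segmentation and objective OSPA measures.

Within the valid epochs of a day, epochs with a count at or above
``active_count_threshold`` are movement epochs.  A maximal movement run of at
least ``min_ambulatory_epochs`` (default 4 epochs = 1 min) becomes an
*ambulatory* bout; shorter movement runs — desk fidgeting — are absorbed into
the surrounding *stationary* time.  Invalid epochs form *invalid* bouts and
terminate any open bout: a stationary stretch split by a data dropout is two
bouts, never one, so unknown gaps can never fabricate prolonged sitting.

"Stationary" deliberately pools sitting and standing (any waking behavior
with no ambulation); wrist counts cannot separate postures.  The objective
occupational sitting and physical activity (OSPA) measures per day are the
accumulated stationary and ambulatory minutes and the number and accumulated
duration of *prolonged* stationary bouts (>= 60 min, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._runs import maximal_runs
from .config import AlgorithmConfig
from .streams import EpochSeries
from .validity import ValidityMask

__all__ = [
    "Bout",
    "DayOSPA",
    "segment_day",
    "day_ospa",
    "cohort_ospa",
    "STATIONARY",
    "AMBULATORY",
    "INVALID",
]

logger = logging.getLogger(__name__)

STATIONARY = "stationary"
AMBULATORY = "ambulatory"
INVALID = "invalid"


@dataclass(frozen=True)
class Bout:
    """A maximal half-open run [start_epoch, end_epoch) of same-labelled epochs."""

    participant: str
    day: int
    start_epoch: int
    end_epoch: int
    label: str
    epoch_seconds: int = 15

    def __post_init__(self) -> None:
        if not self.start_epoch < self.end_epoch:
            raise ValueError("bout must satisfy start_epoch < end_epoch")
        if self.label not in (STATIONARY, AMBULATORY, INVALID):
            raise ValueError(f"unknown bout label {self.label!r}")

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    @property
    def duration_minutes(self) -> float:
        return self.n_epochs * self.epoch_seconds / 60.0


@dataclass(frozen=True)
class DayOSPA:
    """Objective OSPA aggregates for one day."""

    participant: str
    day: int
    stationary_minutes: float
    ambulatory_minutes: float
    n_prolonged_bouts: int
    prolonged_minutes: float


def segment_day(
    series: EpochSeries, mask: ValidityMask, config: AlgorithmConfig
) -> list[Bout]:
    """Segment one day into an ordered, tiling list of bouts.

    The returned bouts are non-overlapping, cover every epoch of the day and
    adjacent bouts carry different labels.
    """
    counts = series.counts
    if len(mask) != counts.size:
        raise ValueError(
            f"mask length {len(mask)} does not match series length {counts.size}"
        )
    # 0=stationary, 1=ambulatory, 2=invalid
    labels = np.zeros(counts.size, dtype=np.int8)
    labels[~mask.valid] = 2
    movement = (counts >= config.active_count_threshold) & mask.valid
    for start, end in maximal_runs(movement):
        if end - start >= config.min_ambulatory_epochs:
            labels[start:end] = 1

    names = (STATIONARY, AMBULATORY, INVALID)
    bouts: list[Bout] = []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    edges = [0, *boundaries.tolist(), counts.size]
    for start, end in zip(edges, edges[1:]):
        bouts.append(
            Bout(
                participant=series.participant,
                day=series.day,
                start_epoch=start,
                end_epoch=end,
                label=names[labels[start]],
                epoch_seconds=config.epoch_seconds,
            )
        )
    return bouts


def day_ospa(bouts: Sequence[Bout], config: AlgorithmConfig) -> DayOSPA:
    """Accumulate one day's bouts into the objective OSPA measures.

    A stationary bout is prolonged when its duration is at least
    ``prolonged_bout_minutes`` — the 60-min boundary itself is prolonged.
    """
    stationary = ambulatory = prolonged = 0.0
    n_prolonged = 0
    for b in bouts:
        if b.label == STATIONARY:
            stationary += b.duration_minutes
            if b.duration_minutes >= config.prolonged_bout_minutes:
                n_prolonged += 1
                prolonged += b.duration_minutes
        elif b.label == AMBULATORY:
            ambulatory += b.duration_minutes
    participant = bouts[0].participant if bouts else ""
    day = bouts[0].day if bouts else 0
    return DayOSPA(
        participant=participant,
        day=day,
        stationary_minutes=stationary,
        ambulatory_minutes=ambulatory,
        n_prolonged_bouts=n_prolonged,
        prolonged_minutes=prolonged,
    )


def cohort_ospa(valid_days: Iterable[DayOSPA]) -> pd.DataFrame:
    """Per-participant means of each OSPA measure over *valid* days only.

    Callers are responsible for restricting ``valid_days`` to valid tracking
    days; participants contributing zero valid days simply do not appear
    (a warning is logged when the input is empty).
    """
    rows = [
        {
            "participant": d.participant,
            "stationary_minutes": d.stationary_minutes,
            "ambulatory_minutes": d.ambulatory_minutes,
            "n_prolonged_bouts": d.n_prolonged_bouts,
            "prolonged_minutes": d.prolonged_minutes,
        }
        for d in valid_days
    ]
    if not rows:
        logger.warning("cohort_ospa: no valid days supplied; empty table")
        return pd.DataFrame(
            columns=[
                "participant",
                "stationary_minutes",
                "ambulatory_minutes",
                "n_prolonged_bouts",
                "prolonged_minutes",
                "n_valid_days",
            ]
        ).set_index("participant")
    df = pd.DataFrame(rows)
    out = df.groupby("participant").mean()
    out["n_valid_days"] = df.groupby("participant").size()
    return out


def bouts_to_dataframe(bouts: Iterable[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": b.participant,
            "day": b.day,
            "start_epoch": b.start_epoch,
            "end_epoch": b.end_epoch,
            "label": b.label,
            "duration_min": b.duration_minutes,
        }
        for b in bouts
    )
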