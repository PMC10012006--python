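"""Epoch-count streams: the pipeline's input unit and its CSV dialect.

An :class:`EpochSeries` is one workday of non-negative activity counts for
one participant on a contiguous fixed grid (default one count per 15-s
epoch).  Missing transmission is encoded as count 0 by the recording system,
so the grid never has gaps; loss of data shows up downstream as invalid
tracking, never as absent rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochSeries", "read_epoch_csv", "write_epoch_csv"]

#: Column schema of a per-participant-day epoch CSV.
EPOCH_CSV_COLUMNS = ("timestamp_iso", "epoch_index", "count")

_DEFAULT_START = datetime(2000, 1, 1, 9, 0, 0)


@dataclass(frozen=True)
class EpochSeries:
    """One workday of activity counts on a fixed epoch grid.

    Parameters
    ----------
    participant
        Participant identifier, e.g. ``"P03"``.
    day
        Workday index within the observation window (0-based).
    counts
        Non-negative integer activity counts, one per epoch, length >= 1.
    start_time
        Wall-clock time of the first epoch's start.
    """

    participant: str
    day: int
    counts: np.ndarray
    start_time: datetime = _DEFAULT_START

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if (counts < 0).any():
            raise ValueError("activity counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return int(self.counts.size)

    def to_dataframe(self, epoch_seconds: int = 15) -> pd.DataFrame:
        stamps = [
            (self.start_time + timedelta(seconds=i * epoch_seconds)).isoformat()
            for i in range(len(self))
        ]
        return pd.DataFrame(
            {
                "timestamp_iso": stamps,
                "epoch_index": np.arange(len(self)),
                "count": self.counts,
            }
        )


def write_epoch_csv(series: EpochSeries, path: str | Path, epoch_seconds: int = 15) -> None:
    series.to_dataframe(epoch_seconds).to_csv(path, index=False)


def read_epoch_csv(path: str | Path, participant: str, day: int) -> EpochSeries:
    """Load one participant-day stream written by :func:`write_epoch_csv`."""
    df = pd.read_csv(path)
    missing = set(EPOCH_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("epoch_index")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        raise ValueError(f"{path}: epoch_index must be the contiguous range 0..n-1")
    start = datetime.fromisoformat(str(df["timestamp_iso"].iloc[0]))
    return EpochSeries(
        participant=participant,
        day=day,
        counts=df["count"].to_numpy(),
        start_time=start,
    )
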