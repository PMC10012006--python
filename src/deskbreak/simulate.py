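"""Synthetic office-workday count streams with known ground truth.

No participant-level data accompany studies of this kind, so every
downstream stage is exercised on simulated streams that emulate the study's
conditions: 15 participants, 30 possible workdays of 480 min, alternating
sitting and break intervals from a semi-Markov (alternating renewal) model
with gamma-distributed durations, Bluetooth-style dropout as zero-count
runs, and a probabilistic behavioural response to the 45-min prompt.

Texture of a sitting interval: runs of zero-count epochs with geometric
length (mean ~9 epochs, capped just below the invalid-run rule) separated by
single count-1 "fidget" epochs.  Roughly 90% of sitting epochs are zero, yet
an uninterrupted sitting stretch can never be misread as invalid tracking —
only dropout produces invalid runs.  Setting ``sitting_zero_prob = 1``
disables fidgets (pure-zero sitting) for callers who want that degenerate
regime.  Break epochs always carry counts at or above the movement
threshold.

Prompt response is simulated mechanistically: when a drawn sitting duration
would cross the amber threshold (45 min), the bout is truncated, with
probability ``responsiveness``, at 45 min plus a uniform latency in
(0, compliance window]; otherwise the full duration stands and any break
that eventually follows is a coincidental response.  This makes compliance a
recoverable parameter of the stream.

Determinism: the stream for (seed, participant, day) is bit-exact across
runs and platforms — counts are integers and every sampled duration is
rounded to whole epochs before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import AlgorithmConfig
from .streams import EpochSeries, write_epoch_csv

__all__ = ["GeneratorParams", "GroundTruth", "generate_day", "generate_cohort"]

SITTING = "sitting"
BREAK = "break"
DROPOUT = "dropout"


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions of the simulated study.

    Defaults mirror the feasibility-study setting: 15 office workers, 30
    possible tracking workdays of 8 h, long skewed sitting bouts (mean
    50 min) interleaved with short breaks (mean 5 min), occasional
    connectivity dropouts, and a moderately responsive wearer.

    ``sitting_bout_dispersion`` is the squared coefficient of variation of
    the gamma duration distributions (shape = 1/dispersion); the default
    0.25 gives shape 4, a realistic right skew.
    """

    n_participants: int = 15
    n_days: int = 30
    workday_minutes: float = 480.0
    mean_sitting_bout_minutes: float = 50.0
    mean_break_minutes: float = 5.0
    sitting_bout_dispersion: float = 0.25
    sitting_zero_prob: float = 0.9
    dropout_prob_per_epoch: float = 0.0008
    mean_dropout_minutes: float = 15.0
    responsiveness: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("workday_minutes", "mean_sitting_bout_minutes",
                     "mean_break_minutes", "mean_dropout_minutes",
                     "sitting_bout_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sitting_zero_prob", "dropout_prob_per_epoch", "responsiveness"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.n_participants < 0 or self.n_days < 0:
            raise ValueError("n_participants and n_days must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """True behaviour intervals of one simulated day.

    ``intervals`` are half-open epoch ranges (start, end, label) with label
    in {sitting, break, dropout}; they tile the workday without overlap.
    """

    participant: str
    day: int
    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        pos = 0
        for start, end, label in self.intervals:
            if start != pos or end <= start:
                raise ValueError("ground-truth intervals must tile the workday")
            if label not in (SITTING, BREAK, DROPOUT):
                raise ValueError(f"unknown ground-truth label {label!r}")
            pos = end

    @property
    def n_epochs(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0


def _participant_id(index: int) -> str:
    return f"P{index + 1:02d}"


def _duration_epochs(rng: np.random.Generator, mean_minutes: float,
                     dispersion: float, epoch_seconds: int) -> int:
    shape = 1.0 / dispersion
    minutes = rng.gamma(shape, mean_minutes * dispersion)
    return max(1, round(minutes * 60.0 / epoch_seconds))


def generate_day(
    params: GeneratorParams,
    participant: int,
    day: int,
    config: AlgorithmConfig | None = None,
) -> tuple[EpochSeries, GroundTruth]:
    """Simulate one participant-workday; deterministic in (seed, participant, day)."""
    config = config or AlgorithmConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, participant, day])
    )
    n_epochs = config.minutes_to_epochs(params.workday_minutes)
    epoch_s = config.epoch_seconds
    amber_epochs = config.amber_start_epochs
    window_epochs = config.minutes_to_epochs(config.compliance_latency_minutes)

    # -- alternating sitting/break schedule --------------------------------
    schedule: list[tuple[int, str]] = []  # (n_epochs, label)
    total = 0
    state = SITTING
    while total < n_epochs:
        if state == SITTING:
            n = _duration_epochs(rng, params.mean_sitting_bout_minutes,
                                 params.sitting_bout_dispersion, epoch_s)
            # behavioural response: truncate a bout that would get prompted
            if n > amber_epochs and rng.random() < params.responsiveness:
                latency_epochs = 1 + rng.integers(window_epochs)
                n = amber_epochs + int(latency_epochs)
        else:
            n = _duration_epochs(rng, params.mean_break_minutes,
                                 params.sitting_bout_dispersion, epoch_s)
        n = min(n, n_epochs - total)
        schedule.append((n, state))
        total += n
        state = BREAK if state == SITTING else SITTING

    # -- counts ------------------------------------------------------------
    counts = np.zeros(n_epochs, dtype=np.int64)
    labels = np.empty(n_epochs, dtype=object)
    pos = 0
    for n, label in schedule:
        labels[pos:pos + n] = label
        if label == BREAK:
            counts[pos:pos + n] = config.active_count_threshold + rng.poisson(
                25, size=n
            )
        else:
            counts[pos:pos + n] = _sitting_texture(rng, n, params, config)
        pos += n

    # -- dropout overlay ---------------------------------------------------
    if params.dropout_prob_per_epoch > 0:
        starts = rng.random(n_epochs)
        pos = 0
        while pos < n_epochs:
            if starts[pos] < params.dropout_prob_per_epoch:
                length = _duration_epochs(rng, params.mean_dropout_minutes,
                                          params.sitting_bout_dispersion, epoch_s)
                end = min(pos + length, n_epochs)
                counts[pos:end] = 0
                labels[pos:end] = DROPOUT
                pos = end
            else:
                pos += 1

    pid = _participant_id(participant)
    intervals: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, n_epochs + 1):
        if i == n_epochs or labels[i] != labels[start]:
            intervals.append((start, i, str(labels[start])))
            start = i
    series = EpochSeries(participant=pid, day=day, counts=counts)
    truth = GroundTruth(participant=pid, day=day, intervals=tuple(intervals))
    return series, truth


def _sitting_texture(
    rng: np.random.Generator, n: int, params: GeneratorParams,
    config: AlgorithmConfig,
) -> np.ndarray:
    """Zero-runs separated by single sub-ambulatory fidget epochs."""
    if params.sitting_zero_prob >= 1.0:
        return np.zeros(n, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    max_run = config.invalid_run_epochs - 1
    fidget_hi = config.active_count_threshold  # exclusive
    pos = 0
    while pos < n:
        run = int(rng.geometric(1.0 - params.sitting_zero_prob))
        run = min(run, max_run)
        pos += run
        if pos < n:
            if fidget_hi > 1:
                out[pos] = int(rng.integers(1, fidget_hi))
            else:
                out[pos] = 1
            pos += 1
    return out


def generate_cohort(
    params: GeneratorParams,
    out_dir: str | Path | None = None,
    config: AlgorithmConfig | None = None,
) -> tuple[list[tuple[EpochSeries, GroundTruth]], pd.DataFrame]:
    """All n_participants x n_days streams plus a manifest table.

    With ``out_dir`` given, writes one epoch CSV per participant-day, a
    pooled ground-truth CSV and ``manifest.csv`` listing every file with its
    (participant, day, seed) provenance.
    """
    config = config or AlgorithmConfig()
    days: list[tuple[EpochSeries, GroundTruth]] = []
    manifest_rows = []
    truth_rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for p in range(params.n_participants):
        for d in range(params.n_days):
            series, truth = generate_day(params, p, d, config)
            days.append((series, truth))
            fname = f"epochs_{series.participant}_d{d:02d}.csv"
            manifest_rows.append(
                {"participant": series.participant, "day": d,
                 "seed": params.seed, "file": fname}
            )
            for start, end, label in truth.intervals:
                truth_rows.append(
                    {"participant": series.participant, "day": d,
                     "start_epoch": start, "end_epoch": end, "label": label}
                )
            if out_path is not None:
                write_epoch_csv(series, out_path / fname, config.epoch_seconds)
    manifest = pd.DataFrame(
        manifest_rows, columns=["participant", "day", "seed", "file"]
    )
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        pd.DataFrame(
            truth_rows,
            columns=["participant", "day", "start_epoch", "end_epoch", "label"],
        ).to_csv(out_path / "ground_truth.csv", index=False)
    return days, manifest
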