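"""Algorithm configuration: every threshold in one auditable, serialisable place.

All stages of the pipeline read their constants from :class:`AlgorithmConfig`
rather than hard-coding them, because deployments of LED-prompt systems are
routinely re-tuned per user (count threshold, prompt timing).  Durations are
stored in the units practitioners quote (seconds for the epoch grid, minutes
for everything else) and validated to be exact multiples of the epoch length,
so every downstream computation is integer epoch arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["AlgorithmConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for malformed config files or invariant violations."""


_GRANULARITIES = ("per_stage", "per_episode")


@dataclass(frozen=True)
class AlgorithmConfig:
    """Thresholds and conventions shared by every pipeline stage.

    Attributes
    ----------
    epoch_seconds
        Length of the fixed reporting window of the wrist sensor (15 s).
    invalid_run_epochs
        A maximal run of this many (or more) consecutive zero-count epochs is
        classified as invalid tracking (40 epochs = 10 min of no data,
        attributed to disconnection or non-wear).
    valid_day_min_valid_minutes, valid_day_max_invalid_minutes
        A tracking day is a *valid tracking day* iff valid time strictly
        exceeds the first bound and invalid time is strictly below the second
        (both default 180 min, i.e. the 3-hour rule).
    active_count_threshold
        Epochs with a count at or above this are movement epochs.  Default 1:
        any nonzero count is movement.  Exposed because deployed systems
        raised it on user request.
    min_ambulatory_epochs
        Shortest movement run (4 epochs = 1 min) that forms an ambulatory
        bout; shorter runs are absorbed into the flanking stationary time.
    amber_start_minutes, red_start_minutes, flash_start_minutes
        Escalating prompt stages of the LED reminder: amber breathing at
        45 min of uninterrupted inactivity, red breathing at 55, red flashing
        once inactivity exceeds 60.
    prolonged_bout_minutes
        A stationary bout lasting this long *or above* is prolonged (60 min).
    compliance_latency_minutes
        A prompt answered by an ambulatory-bout onset within this latency
        (inclusive, 15 min) counts as complied with.
    possible_tracking_days
        Denominator of adherence (30 intervention workdays).
    latency_bin_edges_minutes
        Right-closed histogram edges for response latency; must increase
        strictly and end at ``compliance_latency_minutes``.
    prompt_granularity
        ``per_stage`` logs one event per stage crossing (a fully ignored hour
        logs three events); ``per_episode`` logs only the first crossing of
        each uninterrupted stationary episode.
    """

    epoch_seconds: int = 15
    invalid_run_epochs: int = 40
    valid_day_min_valid_minutes: float = 180.0
    valid_day_max_invalid_minutes: float = 180.0
    active_count_threshold: int = 1
    min_ambulatory_epochs: int = 4
    amber_start_minutes: float = 45.0
    red_start_minutes: float = 55.0
    flash_start_minutes: float = 60.0
    prolonged_bout_minutes: float = 60.0
    compliance_latency_minutes: float = 15.0
    possible_tracking_days: int = 30
    latency_bin_edges_minutes: tuple[float, ...] = (5.0, 10.0, 15.0)
    prompt_granularity: str = "per_stage"

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ConfigError("epoch_seconds must be positive")
        if self.invalid_run_epochs < 1:
            raise ConfigError("invalid_run_epochs must be >= 1")
        if self.active_count_threshold < 1:
            raise ConfigError("active_count_threshold must be >= 1")
        if self.min_ambulatory_epochs < 1:
            raise ConfigError("min_ambulatory_epochs must be >= 1")
        if self.possible_tracking_days < 0:
            raise ConfigError("possible_tracking_days must be >= 0")
        if not (
            self.amber_start_minutes
            < self.red_start_minutes
            < self.flash_start_minutes
        ):
            raise ConfigError(
                "prompt stages must be ordered: amber_start_minutes < "
                "red_start_minutes < flash_start_minutes"
            )
        for name in (
            "valid_day_min_valid_minutes",
            "valid_day_max_invalid_minutes",
            "amber_start_minutes",
            "red_start_minutes",
            "flash_start_minutes",
            "prolonged_bout_minutes",
            "compliance_latency_minutes",
        ):
            minutes = getattr(self, name)
            if minutes <= 0:
                raise ConfigError(f"{name} must be positive")
            if (minutes * 60) % self.epoch_seconds != 0:
                raise ConfigError(
                    f"{name}={minutes} is not a whole number of "
                    f"{self.epoch_seconds}-s epochs"
                )
        edges = self.latency_bin_edges_minutes
        if any(b <= a for a, b in zip(edges, edges[1:])) or not edges:
            raise ConfigError("latency_bin_edges_minutes must increase strictly")
        if edges[-1] != self.compliance_latency_minutes:
            raise ConfigError(
                "latency_bin_edges_minutes must end at compliance_latency_minutes"
            )
        if self.prompt_granularity not in _GRANULARITIES:
            raise ConfigError(
                f"prompt_granularity must be one of {_GRANULARITIES}"
            )

    # -- epoch arithmetic ---------------------------------------------------

    def minutes_to_epochs(self, minutes: float) -> int:
        """Convert a duration in minutes to an exact number of epochs."""
        seconds = minutes * 60
        n, rem = divmod(seconds, self.epoch_seconds)
        if rem:
            raise ConfigError(
                f"{minutes} min is not a whole number of {self.epoch_seconds}-s epochs"
            )
        return int(n)

    def epochs_to_minutes(self, n_epochs: int) -> float:
        return n_epochs * self.epoch_seconds / 60.0

    @property
    def amber_start_epochs(self) -> int:
        return self.minutes_to_epochs(self.amber_start_minutes)

    @property
    def red_start_epochs(self) -> int:
        return self.minutes_to_epochs(self.red_start_minutes)

    @property
    def flash_start_epochs(self) -> int:
        return self.minutes_to_epochs(self.flash_start_minutes)

    @property
    def prolonged_bout_epochs(self) -> int:
        return self.minutes_to_epochs(self.prolonged_bout_minutes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["latency_bin_edges_minutes"] = list(self.latency_bin_edges_minutes)
        return d


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(AlgorithmConfig)}


def load_config(path: str | Path | None = None) -> AlgorithmConfig:
    """Return defaults overridden by the flat YAML mapping at ``path``.

    Unknown keys are rejected so a typo cannot silently leave a threshold at
    its default.  Invariant violations raise :class:`ConfigError` naming the
    offending field.
    """
    if path is None:
        return AlgorithmConfig()
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message formatting
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config file {path}{line}: {exc}") from exc
    if raw is None:
        return AlgorithmConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key-value mapping")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "latency_bin_edges_minutes" in raw:
        raw["latency_bin_edges_minutes"] = tuple(
            float(v) for v in raw["latency_bin_edges_minutes"]
        )
    return AlgorithmConfig(**raw)


def save_config(config: AlgorithmConfig, path: str | Path) -> None:
    """Write ``config`` as flat YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=None)
    )
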