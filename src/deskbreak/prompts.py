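"""Replay of the LED reminder state machine and prompt-response matching.

The cup LED escalates with uninterrupted inactivity: amber breathing once the
wearer has been inactive 45 min ("you can consider a break now!"), red
breathing at 55 min, red flashing once inactivity exceeds 60 min.  This
module replays those rules over a segmented day: an inactivity clock runs
from the start of each stationary bout, emits one event at each stage
crossing, and resets at every ambulatory-bout onset.  Invalid bouts also
reset the clock and suppress events — with no connectivity the LED cannot
light up.

A stage crossing fires at the first epoch whose start lies at or beyond the
stage threshold, provided that epoch is still inside the stationary bout; a
bout of exactly 45.0 min therefore emits nothing (the wearer moved at the
threshold instant) while a 65-min bout emits all three stages at minutes
45, 55 and 60.

The behavioural *response* to a prompt is the onset of the next ambulatory
bout at or after the trigger, regardless of cause; the elapsed time is the
*response latency*.  A prompt with no subsequent ambulatory onset that day
has latency ``None`` and counts as non-complied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .bouts import AMBULATORY, STATIONARY, Bout
from .config import AlgorithmConfig

__all__ = [
    "PromptEvent",
    "PromptResponse",
    "run_state_machine",
    "match_responses",
    "STAGES",
]

#: Escalation stages in trigger order.
STAGES = ("amber_breathing", "red_breathing", "red_flashing")


@dataclass(frozen=True)
class PromptEvent:
    participant: str
    day: int
    epoch: int
    stage: str
    inactivity_minutes_at_trigger: float


@dataclass(frozen=True)
class PromptResponse:
    prompt: PromptEvent
    response_epoch: int | None
    latency_minutes: float | None

    def __post_init__(self) -> None:
        if self.response_epoch is not None and self.response_epoch < self.prompt.epoch:
            raise ValueError("response cannot precede its prompt")


def run_state_machine(
    bouts: Sequence[Bout], config: AlgorithmConfig
) -> list[PromptEvent]:
    """Emit the ordered prompt events for one day's bouts.

    With ``prompt_granularity == "per_episode"`` only the first stage crossing
    of each stationary bout is logged (one event per escalation episode);
    the default ``"per_stage"`` logs every crossing.
    """
    thresholds = [
        (STAGES[0], config.amber_start_epochs, config.amber_start_minutes),
        (STAGES[1], config.red_start_epochs, config.red_start_minutes),
        (STAGES[2], config.flash_start_epochs, config.flash_start_minutes),
    ]
    events: list[PromptEvent] = []
    for bout in bouts:
        if bout.label != STATIONARY:
            continue
        for stage, t_epochs, t_minutes in thresholds:
            trigger = bout.start_epoch + t_epochs
            if trigger < bout.end_epoch:
                events.append(
                    PromptEvent(
                        participant=bout.participant,
                        day=bout.day,
                        epoch=trigger,
                        stage=stage,
                        inactivity_minutes_at_trigger=t_minutes,
                    )
                )
                if config.prompt_granularity == "per_episode":
                    break
    return events


def match_responses(
    events: Sequence[PromptEvent],
    bouts: Sequence[Bout],
    config: AlgorithmConfig,
) -> list[PromptResponse]:
    """Pair each prompt with the first ambulatory-bout onset at or after it."""
    onsets = [b.start_epoch for b in bouts if b.label == AMBULATORY]
    responses: list[PromptResponse] = []
    for event in events:
        onset = next((o for o in onsets if o >= event.epoch), None)
        if onset is None:
            responses.append(PromptResponse(event, None, None))
        else:
            latency = (onset - event.epoch) * config.epoch_seconds / 60.0
            responses.append(PromptResponse(event, onset, latency))
    return responses
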