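"""Pre/post outcome scoring and paired comparisons.

Self-report occupational sitting and physical activity (OSPA) is scored by
pooling postures: stationary = sitting + standing, ambulatory = walking +
heavy labor.  Psychosocial constructs (intention, perceived behavioral
control, barriers, facilitators, automaticity of break habits, retrospective
and prospective memory of breaks, work-fatigue subscales) are means of
7-point Likert items (1 = strongly disagree .. 7 = strongly agree).
Reverse-keyed constructs are analysed in their raw direction; the sign is
interpreted at reporting time.

Pre/post change is assessed with classical paired-samples t tests on
post - pre differences, two-sided, alpha = .05, df = n - 1.  Participants
missing either phase are dropped pairwise with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyRecord",
    "PairedTestResult",
    "score_self_report_ospa",
    "score_construct",
    "paired_t",
    "prepost_table",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class SurveyRecord:
    """One participant's survey responses for one phase (pre or post).

    ``ospa_minutes`` maps posture -> daily minutes (keys among ``sitting``,
    ``standing``, ``walking``, ``heavy_labor``); ``likert_items`` maps a
    construct name to its list of 1-7 item responses.
    """

    participant: str
    phase: str
    ospa_minutes: Mapping[str, float] = field(default_factory=dict)
    likert_items: Mapping[str, Sequence[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        for minutes in self.ospa_minutes.values():
            if minutes is not None and minutes < 0:
                raise ValueError("OSPA minutes must be non-negative")
        for construct, items in self.likert_items.items():
            if any(not (1 <= v <= 7) for v in items):
                raise ValueError(f"Likert items for {construct!r} must be in 1..7")


@dataclass(frozen=True)
class PairedTestResult:
    measure: str
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def score_self_report_ospa(record: SurveyRecord) -> tuple[float | None, float | None]:
    """(stationary, ambulatory) daily minutes from the posture items.

    stationary = sitting + standing; ambulatory = walking + heavy_labor.
    A missing posture makes the corresponding total missing (``None``);
    nothing is zero-filled.
    """

    def total(keys: tuple[str, str]) -> float | None:
        vals = [self_minutes.get(k) for k in keys]
        if any(v is None for v in vals):
            return None
        return float(sum(vals))

    self_minutes = dict(record.ospa_minutes)
    return total(("sitting", "standing")), total(("walking", "heavy_labor"))


def score_construct(record: SurveyRecord, construct: str) -> float | None:
    """Mean of the construct's Likert items, in [1, 7]; ``None`` if absent."""
    items = record.likert_items.get(construct)
    if not items:
        return None
    return float(np.mean(items))


def paired_t(
    pre: Sequence[float], post: Sequence[float], measure: str = ""
) -> PairedTestResult:
    """Classical paired t test on post - pre differences (two-sided).

    Pairs with a missing value are dropped (and logged).  With zero variance
    of the differences the t statistic is reported as signed infinity
    (p = 0) for a nonzero mean difference, and 0 (p = 1) otherwise.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if pre_arr.shape != post_arr.shape:
        raise ValueError("pre and post must be paired (equal length)")
    keep = ~(np.isnan(pre_arr) | np.isnan(post_arr))
    if keep.size != keep.sum():
        logger.warning(
            "paired_t(%s): dropped %d pair(s) with missing values",
            measure, int(keep.size - keep.sum()),
        )
    pre_arr, post_arr = pre_arr[keep], post_arr[keep]
    n = pre_arr.size
    if n < 2:
        raise ValueError("paired_t needs at least 2 complete pairs")
    diff = post_arr - pre_arr
    mean_diff = float(diff.mean())
    if float(diff.std(ddof=1)) == 0.0:
        if mean_diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean_diff), 0.0
    else:
        res = stats.ttest_rel(post_arr, pre_arr)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return PairedTestResult(
        measure=measure,
        pre_mean=float(pre_arr.mean()),
        pre_sd=float(pre_arr.std(ddof=1)),
        post_mean=float(post_arr.mean()),
        post_sd=float(post_arr.std(ddof=1)),
        mean_difference=mean_diff,
        t_statistic=t_stat,
        df=n - 1,
        p_value=p,
    )


def prepost_table(
    objective_pre: pd.DataFrame | None,
    objective_post: pd.DataFrame | None,
    surveys: Sequence[SurveyRecord] = (),
) -> pd.DataFrame:
    """One paired-test row per outcome measure, pre vs post.

    ``objective_pre``/``objective_post`` are per-participant OSPA tables as
    returned by :func:`deskbreak.bouts.cohort_ospa` for the two phases
    (participants in their index).  Survey records contribute self-report
    OSPA totals and one row per Likert construct.  Participants present in
    only one phase are dropped from the affected measure with a warning.
    """
    rows: list[PairedTestResult] = []

    if objective_pre is not None and objective_post is not None:
        shared = objective_pre.index.intersection(objective_post.index)
        dropped = set(objective_pre.index).symmetric_difference(objective_post.index)
        if dropped:
            logger.warning("prepost_table: dropped %s (one phase missing)", sorted(dropped))
        for col in ("stationary_minutes", "ambulatory_minutes",
                    "n_prolonged_bouts", "prolonged_minutes"):
            if col in objective_pre.columns and len(shared) >= 2:
                rows.append(
                    paired_t(
                        objective_pre.loc[shared, col],
                        objective_post.loc[shared, col],
                        measure=f"objective_{col}",
                    )
                )

    if surveys:
        by_phase: dict[str, dict[str, SurveyRecord]] = {"pre": {}, "post": {}}
        for rec in surveys:
            by_phase[rec.phase][rec.participant] = rec
        shared_ids = sorted(set(by_phase["pre"]) & set(by_phase["post"]))
        missing = set(by_phase["pre"]).symmetric_difference(by_phase["post"])
        if missing:
            logger.warning("prepost_table: dropped %s (one survey phase missing)",
                           sorted(missing))
        if len(shared_ids) >= 2:
            for idx, name in ((0, "self_report_stationary_minutes"),
                              (1, "self_report_ambulatory_minutes")):
                pre_vals = [score_self_report_ospa(by_phase["pre"][p])[idx] for p in shared_ids]
                post_vals = [score_self_report_ospa(by_phase["post"][p])[idx] for p in shared_ids]
                if all(v is not None for v in pre_vals + post_vals):
                    rows.append(paired_t(pre_vals, post_vals, measure=name))
            constructs = sorted(
                {c for p in shared_ids for c in by_phase["pre"][p].likert_items}
            )
            for construct in constructs:
                pre_vals = [score_construct(by_phase["pre"][p], construct) for p in shared_ids]
                post_vals = [score_construct(by_phase["post"][p], construct) for p in shared_ids]
                if all(v is not None for v in pre_vals + post_vals):
                    rows.append(paired_t(pre_vals, post_vals, measure=construct))

    table = pd.DataFrame(
        {
            "measure": r.measure,
            "pre_mean": r.pre_mean,
            "pre_sd": r.pre_sd,
            "post_mean": r.post_mean,
            "post_sd": r.post_sd,
            "mean_difference": r.mean_difference,
            "t_statistic": r.t_statistic,
            "df": r.df,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in rows
    )
    return table
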