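"""Human-readable process-evaluation report (markdown).

Numbers are rounded to one decimal at emission only; the CSV outputs keep
full precision.
"""

from __future__ import annotations

from .metrics import latency_histogram, minutes_to_hours

__all__ = ["render_report"]


def _fmt(x, nd: int = 1) -> str:
    if x is None:
        return "n/a"
    return f"{x:.{nd}f}"


def render_report(cohort) -> str:
    """Markdown summary of a processed cohort (a ``pipeline.CohortResult``)."""
    config = cohort.config
    summary = cohort.summary()
    pooled = summary["pooled"]
    responses = cohort.all_responses()
    hist = latency_histogram(responses, config)

    adh = summary["adherence_pct"]
    qual = summary["quality_pct"]
    comp = summary["compliance_pct"]
    td = summary["tracking_days"]

    valid_minutes = [
        d.validity.valid_minutes for d in cohort.days if d.validity.is_valid_day
    ]
    mean_valid_min = (
        sum(valid_minutes) / len(valid_minutes) if valid_minutes else None
    )

    lines = [
        "# Process evaluation report",
        "",
        "## Adherence and quality of tracking",
        "",
        f"- Participants: {len(cohort.participants)}",
        f"- Tracking days: mean {_fmt(td['mean'])} (SD {_fmt(td['sd'])}), "
        f"median {_fmt(td['median'])} ({_fmt(td['p25'])}-{_fmt(td['p75'])}) "
        f"of a possible {config.possible_tracking_days}",
        f"- Adherence: mean {_fmt(adh['mean'])}% (SD {_fmt(adh['sd'])}%), "
        f"median {_fmt(adh['median'])}% ({_fmt(adh['p25'])}%-{_fmt(adh['p75'])}%)",
        f"- Of {pooled['tracking_days']} total tracking days, "
        f"{pooled['valid_days']} ({_fmt(pooled['quality_pct'])}%) were valid "
        "tracking days",
        f"- Quality of tracking per participant: mean {_fmt(qual['mean'])}% "
        f"(SD {_fmt(qual['sd'])}%)",
    ]
    if mean_valid_min is not None:
        lines.append(
            f"- Daily valid tracking time on valid days: mean "
            f"{_fmt(mean_valid_min)} min ({_fmt(minutes_to_hours(mean_valid_min))} h)"
        )
    lines += [
        "",
        "## Prompts and compliance",
        "",
        f"- Total prompts triggered: {pooled['n_prompts']}",
        f"- Responded to within {config.compliance_latency_minutes:g} min: "
        f"{pooled['n_compliant']} ({_fmt(pooled['compliance_pct'])}%)",
        f"- Compliance per participant: mean {_fmt(comp['mean'])}% "
        f"(SD {_fmt(comp['sd'])}%)",
        "",
        "Latency distribution (share of all prompts):",
        "",
    ]
    for label, cell in hist.items():
        lines.append(f"- {label}: n={cell['count']} ({_fmt(cell['pct'])}%)")
    lines.append("")
    return "\n".join(lines)
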