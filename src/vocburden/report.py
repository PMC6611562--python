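"""Descriptive report assembly and rendering.

Collects the cohort, episode, and visit summaries into one machine-readable
structure (JSON) plus a human-readable Markdown rendering.  Percentages are
computed before rounding and rounded half away from zero at one decimal;
rates are reported at fixed precision so repeated runs are byte-identical.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .codesets import StudyConfig
from .cohort import CohortMember
from .episodes import RateSummary, VOCEpisode, episode_rates
from .utilization import Visit, los_summary, percentage, reason_breakdown, round_half_away

__all__ = ["SummaryReport", "build_report", "render"]

_AGE_GROUPS = ((18, 30), (31, 45), (46, 64), (65, 200))
_CCI_BINS = (("0", 0, 0), ("1", 1, 1), ("2-3", 2, 3), ("4+", 4, 10**9))


@dataclass(frozen=True)
class SummaryReport:
    cohort_summary: dict
    episode_summary: dict
    visit_summary: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "cohort_summary": self.cohort_summary,
            "episode_summary": self.episode_summary,
            "visit_summary": self.visit_summary,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SummaryReport":
        return cls(
            cohort_summary=data["cohort_summary"],
            episode_summary=data["episode_summary"],
            visit_summary=data["visit_summary"],
            provenance=data["provenance"],
        )


def _count_pct(counts: dict[str, int], n: int) -> dict[str, dict]:
    return {
        key: {"n": count, "pct": percentage(count, n) if n else 0.0}
        for key, count in counts.items()
    }


def _r(x: float, ndigits: int = 4) -> float:
    return round_half_away(x, ndigits)


def _cohort_block(members: Sequence[CohortMember]) -> dict:
    n = len(members)
    if n == 0:
        return {"n": 0}
    ages = np.array([m.age_at_index for m in members], dtype=float)
    age_groups = {
        f"{lo}-{hi}" if hi < 200 else f"{lo}+": sum(
            1 for m in members if lo <= m.age_at_index <= hi
        )
        for lo, hi in _AGE_GROUPS
    }
    sex = {}
    race = {}
    region = {}
    for m in members:
        sex[m.sex] = sex.get(m.sex, 0) + 1
        race[m.race] = race.get(m.race, 0) + 1
        region[m.region] = region.get(m.region, 0) + 1
    cci = np.array([m.cci for m in members], dtype=float)
    cci_dist = {
        label: sum(1 for m in members if lo <= m.cci <= hi)
        for label, lo, hi in _CCI_BINS
    }
    n_any_er = sum(1 for m in members if m.baseline_er_visits > 0)
    n_any_ip = sum(1 for m in members if m.baseline_ip_stays > 0)
    return {
        "n": n,
        "age_mean": _r(float(ages.mean()), 2),
        "age_sd": _r(float(ages.std(ddof=1)), 2) if n > 1 else 0.0,
        "age_median": _r(float(np.median(ages)), 1),
        "age_groups": _count_pct(age_groups, n),
        "sex": _count_pct(dict(sorted(sex.items())), n),
        "race": _count_pct(dict(sorted(race.items())), n),
        "region": _count_pct(dict(sorted(region.items())), n),
        "cci_mean": _r(float(cci.mean()), 2),
        "cci_distribution": _count_pct(cci_dist, n),
        "baseline": {
            "mean_er_visits": _r(
                float(np.mean([m.baseline_er_visits for m in members])), 2
            ),
            "any_er_visit": {"n": n_any_er, "pct": percentage(n_any_er, n)},
            "any_inpatient_stay": {"n": n_any_ip, "pct": percentage(n_any_ip, n)},
            "mean_ip_los_days": _r(
                float(np.mean([m.baseline_ip_los_days for m in members])), 2
            ),
        },
    }


def _episode_block(
    members: Sequence[CohortMember],
    episodes: Mapping[str, Sequence[VOCEpisode]],
    config: StudyConfig,
) -> dict:
    flat = [e for eps in episodes.values() for e in eps]
    total = len(flat)
    if total == 0:
        return {
            "total_episodes": 0,
            "rate_per_person_year": None,
            "rate_undefined": True,
        }
    rates: RateSummary = episode_rates(members, episodes, config)
    n_comp = sum(1 for e in flat if e.complicated)
    n_uncomp = total - n_comp

    def category_ranking(primary_only: bool) -> dict[str, dict]:
        counts: dict[str, int] = {}
        for e in flat:
            if not e.complicated:
                continue
            cats = e.categories_primary if primary_only else e.categories_any
            for label in cats:
                counts[label] = counts.get(label, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return {
            label: {"n": count, "pct_of_complicated": percentage(count, n_comp)}
            for label, count in ranked
        }

    return {
        "total_episodes": total,
        "complicated": {"n": n_comp, "pct": percentage(n_comp, total)},
        "uncomplicated": {"n": n_uncomp, "pct": percentage(n_uncomp, total)},
        "person_years": _r(rates.person_years, 2),
        "rate_per_person_year": _r(rates.rate_per_person_year, 4),
        "fraction_with_episode_pct": percentage(
            rates.fraction_with_episode * len(members), len(members)
        ),
        "year1_mean_total": _r(rates.year1_mean_total, 4),
        "year1_mean_by_setting": {
            s: _r(v, 4) for s, v in rates.year1_mean_by_setting.items()
        },
        "year1_count_distribution_pct": {
            k: percentage(v * len(members), len(members))
            for k, v in rates.year1_count_distribution.items()
        },
        "top_complications_primary": category_ranking(primary_only=True),
        "top_complications_any": category_ranking(primary_only=False),
    }


def _visit_block(visits: Sequence[Visit]) -> dict:
    return {
        "reason_breakdown": reason_breakdown(visits),
        "los_summary": {
            reason: {
                key: (_r(value, 2) if isinstance(value, float) else value)
                for key, value in block.items()
            }
            for reason, block in los_summary(visits).items()
        },
    }


def build_report(
    members: Sequence[CohortMember],
    episodes: Mapping[str, Sequence[VOCEpisode]],
    visits: Sequence[Visit],
    config: StudyConfig,
    seed: int | None = None,
) -> SummaryReport:
    """Assemble the full descriptive report; deterministic given inputs."""
    member_ids = {m.patient_id for m in members}
    stray = set(episodes) - member_ids
    if stray:
        raise ValueError(
            f"episodes reference patients absent from the cohort: {sorted(stray)[:5]}"
        )
    stray_visits = {v.patient_id for v in visits} - member_ids
    if stray_visits:
        raise ValueError(
            f"visits reference patients absent from the cohort: "
            f"{sorted(stray_visits)[:5]}"
        )
    return SummaryReport(
        cohort_summary=_cohort_block(members),
        episode_summary=_episode_block(members, episodes, config),
        visit_summary=_visit_block(visits),
        provenance={
            "config_hash": config.content_hash(),
            "seed": seed if seed is not None else config.rng_seed,
            "n_members": len(members),
            "n_episodes": sum(len(eps) for eps in episodes.values()),
            "n_visits": len(visits),
        },
    )


def _markdown_table(title: str, rows: Sequence[tuple[str, object]]) -> list[str]:
    lines = [f"## {title}", "", "| item | value |", "| --- | --- |"]
    lines.extend(f"| {key} | {value} |" for key, value in rows)
    lines.append("")
    return lines


def _flatten(prefix: str, value: object, rows: list[tuple[str, object]]) -> None:
    if isinstance(value, dict):
        for key, sub in value.items():
            _flatten(f"{prefix}.{key}" if prefix else str(key), sub, rows)
    else:
        rows.append((prefix, value))


def render(report: SummaryReport, fmt: str, path: str | Path) -> Path:
    """Write *report* as ``json`` or ``markdown``; byte-identical across runs."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
    elif fmt == "markdown":
        lines = ["# Study summary", ""]
        for title, block in (
            ("Cohort", report.cohort_summary),
            ("VOC episodes", report.episode_summary),
            ("SCD-related visits", report.visit_summary),
            ("Provenance", report.provenance),
        ):
            rows: list[tuple[str, object]] = []
            _flatten("", block, rows)
            lines.extend(_markdown_table(title, rows))
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown render format {fmt!r} (use 'json' or 'markdown')")
    return path
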