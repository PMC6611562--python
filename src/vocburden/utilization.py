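"""First-year ER visit and hospitalization attribution.

Inpatient stays are maximal overlapping/abutting runs of inpatient claims.
ER claims are grouped one visit per calendar day; an ER visit that leads to
an admission within the episode gap window (or falls inside a stay) is
folded into the inpatient visit rather than counted separately.  Each
visit's reason comes from the primary diagnosis of its anchor claim: VOC if
it matches the VOC primary-reason set, otherwise SCD complication if it
matches a complication category, otherwise "other" (retained internally,
excluded from SCD-related outputs).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codesets import StudyConfig
from .cohort import Claim, CohortMember, merge_stays, stay_los_days

__all__ = [
    "Visit",
    "build_visits",
    "extract_visits",
    "reason_breakdown",
    "los_summary",
    "write_visits",
    "round_half_away",
    "percentage",
]

ONE_DAY = datetime.timedelta(days=1)
YEAR1_DAYS = 365


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for printed shares).

    Uses decimal arithmetic on ``repr(x)`` so that values written with an
    exact decimal half (e.g. 29.65) round up despite binary representation.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class Visit:
    patient_id: str
    visit_type: str  # "ER" | "inpatient"
    admit: datetime.date
    discharge: datetime.date
    primary_dx: str
    reason: str  # "VOC" | "SCD_complication" | "other"
    reason_category: str | None
    los_days: int | None  # inpatient only

    def __post_init__(self) -> None:
        if self.visit_type not in ("ER", "inpatient"):
            raise ValueError(f"unknown visit_type {self.visit_type!r}")
        if self.admit > self.discharge:
            raise ValueError("visit admit after discharge")


def _classify_reason(
    primary_dx: str, config: StudyConfig
) -> tuple[str, str | None]:
    if config.voc_primary_reason_codes.matches(primary_dx):
        return "VOC", None
    for category in config.complication_categories:
        if category.codeset.matches(primary_dx):
            return "SCD_complication", category.label
    return "other", None


def _anchor(claims: Sequence[Claim]) -> Claim:
    return min(claims, key=lambda c: (c.service_start, c.claim_id))


def build_visits(
    member_claims: Sequence[Claim],
    member: CohortMember,
    config: StudyConfig,
    include_other: bool = False,
) -> list[Visit]:
    """SCD-related ER and inpatient visits in the member's first follow-up
    year.  Set *include_other* to keep visits whose primary diagnosis matches
    neither configured set."""
    lo = member.followup_start
    hi = min(
        member.followup_start + datetime.timedelta(days=YEAR1_DAYS - 1),
        member.followup_end,
    )
    year1 = [c for c in member_claims if lo <= c.service_start <= hi]

    visits: list[Visit] = []
    stays = merge_stays([c for c in year1 if c.place_of_service == "inpatient"])
    for admit, discharge, stay_claims in stays:
        anchor = _anchor(stay_claims)
        reason, category = _classify_reason(anchor.primary_dx, config)
        visits.append(
            Visit(
                patient_id=member.patient_id,
                visit_type="inpatient",
                admit=admit,
                discharge=discharge,
                primary_dx=anchor.primary_dx,
                reason=reason,
                reason_category=category,
                los_days=stay_los_days(admit, discharge),
            )
        )

    gap = datetime.timedelta(days=config.episode_gap_days)
    er_by_day: dict[datetime.date, list[Claim]] = {}
    for claim in year1:
        if claim.place_of_service == "ER":
            er_by_day.setdefault(claim.service_start, []).append(claim)
    for day in sorted(er_by_day):
        absorbed = any(
            admit - gap <= day <= discharge for admit, discharge, _ in stays
        )
        if absorbed:
            continue
        anchor = _anchor(er_by_day[day])
        reason, category = _classify_reason(anchor.primary_dx, config)
        visits.append(
            Visit(
                patient_id=member.patient_id,
                visit_type="ER",
                admit=day,
                discharge=max(c.service_end for c in er_by_day[day]),
                primary_dx=anchor.primary_dx,
                reason=reason,
                reason_category=category,
                los_days=None,
            )
        )

    visits.sort(key=lambda v: (v.admit, v.visit_type))
    if not include_other:
        visits = [v for v in visits if v.reason != "other"]
    return visits


def extract_visits(
    members: Sequence[CohortMember],
    claims_map: Mapping[str, Sequence[Claim]],
    config: StudyConfig,
    include_other: bool = False,
) -> list[Visit]:
    out: list[Visit] = []
    for m in members:
        out.extend(
            build_visits(claims_map.get(m.patient_id, []), m, config, include_other)
        )
    return out


def reason_breakdown(visits: Sequence[Visit]) -> dict[str, dict]:
    """Counts and percentages by reason, per visit type, plus a category
    split within complication-reason visits.  Empty inputs yield an empty
    breakdown (no division by zero)."""
    out: dict[str, dict] = {}
    for vtype in ("ER", "inpatient"):
        group = [v for v in visits if v.visit_type == vtype and v.reason != "other"]
        n = len(group)
        if n == 0:
            out[vtype] = {"n_total": 0}
            continue
        n_voc = sum(1 for v in group if v.reason == "VOC")
        n_comp = n - n_voc
        cats: dict[str, int] = {}
        for v in group:
            if v.reason == "SCD_complication" and v.reason_category:
                cats[v.reason_category] = cats.get(v.reason_category, 0) + 1
        out[vtype] = {
            "n_total": n,
            "n_VOC": n_voc,
            "n_complication": n_comp,
            "pct_VOC": percentage(n_voc, n),
            "pct_complication": percentage(n_comp, n),
            "category_pct": {
                label: percentage(count, n_comp)
                for label, count in sorted(cats.items())
            }
            if n_comp
            else {},
        }
    return out


def los_summary(visits: Sequence[Visit]) -> dict[str, dict]:
    """Per reason class (inpatient visits only): mean, sample SD (n-1),
    median, and IQR (Q3 - Q1, linear-interpolation quantiles)."""
    out: dict[str, dict] = {}
    for reason in ("VOC", "SCD_complication"):
        los = [
            v.los_days for v in visits
            if v.visit_type == "inpatient" and v.reason == reason
            and v.los_days is not None
        ]
        if not los:
            out[reason] = {"n": 0}
            continue
        arr = np.asarray(los, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[reason] = {
            "n": len(los),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(los) > 1 else 0.0,
            "median": float(med),
            "iqr": float(q3 - q1),
            "single_observation": len(los) == 1,
        }
    return out


def write_visits(visits: Sequence[Visit], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "visit_type": v.visit_type,
                "admit": v.admit.isoformat(),
                "discharge": v.discharge.isoformat(),
                "primary_dx": v.primary_dx,
                "reason": v.reason,
                "reason_category": v.reason_category or "",
                "los_days": "" if v.los_days is None else v.los_days,
            }
            for v in visits
        ],
        columns=["patient_id", "visit_type", "admit", "discharge",
                 "primary_dx", "reason", "reason_category", "los_days"],
    )
    df.to_csv(path, index=False)
    return path
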