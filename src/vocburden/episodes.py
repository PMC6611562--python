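"""VOC episode construction, setting assignment, and classification.

Claims carrying a VOC episode code (any diagnosis position) are merged into
episodes whenever the next claim starts within ``episode_gap_days`` of the
running episode end; a strictly larger gap starts a new episode.  Each
episode takes the highest-priority place of service among its member claims,
and is complicated iff any claim intersecting its closed date interval
carries a complication-category code.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codesets import ConfigError, StudyConfig
from .cohort import Claim, CohortMember

__all__ = [
    "VOCEpisode",
    "RateSummary",
    "build_episodes",
    "assign_setting",
    "classify_episode",
    "extract_episodes",
    "episode_rates",
    "write_episodes",
]

ONE_DAY = datetime.timedelta(days=1)
YEAR1_DAYS = 365


@dataclass(frozen=True)
class VOCEpisode:
    patient_id: str
    start: datetime.date
    end: datetime.date
    claim_ids: tuple[str, ...]
    setting: str
    complicated: bool
    categories_primary: frozenset[str]
    categories_any: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("episode start after end")
        if not self.claim_ids:
            raise ValueError("episode without claims")
        if not self.categories_primary <= self.categories_any:
            raise ValueError("categories_primary must be a subset of categories_any")
        if self.complicated != bool(self.categories_any):
            raise ValueError("complicated flag inconsistent with categories_any")

    @property
    def n_claims(self) -> int:
        return len(self.claim_ids)


def _merge_voc_claims(
    claims: Sequence[Claim], gap_days: int
) -> list[list[Claim]]:
    """Greedy chronological merge of VOC claims into clusters."""
    ordered = sorted(claims, key=lambda c: (c.service_start, c.service_end, c.claim_id))
    clusters: list[list[Claim]] = []
    running_end: datetime.date | None = None
    for claim in ordered:
        if (
            running_end is not None
            and (claim.service_start - running_end).days <= gap_days
        ):
            clusters[-1].append(claim)
            running_end = max(running_end, claim.service_end)
        else:
            clusters.append([claim])
            running_end = claim.service_end
    return clusters


def assign_setting(claims: Sequence[Claim], hierarchy: Sequence[str]) -> str:
    """Highest-priority place of service among *claims* (hierarchy order =
    priority order).  Order of the claim list is immaterial."""
    if not claims:
        raise ValueError("cannot assign a setting to an empty claim list")
    priorities = []
    for claim in claims:
        try:
            priorities.append(hierarchy.index(claim.place_of_service))
        except ValueError:
            raise ConfigError(
                f"claim {claim.claim_id}: place of service "
                f"{claim.place_of_service!r} not in hierarchy"
            )
    return hierarchy[min(priorities)]


def classify_episode(
    start: datetime.date,
    end: datetime.date,
    patient_claims: Sequence[Claim],
    config: StudyConfig,
) -> tuple[bool, frozenset[str], frozenset[str]]:
    """Scan every claim whose service interval intersects [start, end] for
    complication-category codes.

    Returns (complicated, categories_primary, categories_any): a category is
    "primary" when one of its codes appears in diagnosis position 1, "any"
    when it appears in any position.
    """
    primary: set[str] = set()
    any_pos: set[str] = set()
    for claim in patient_claims:
        if claim.service_end < start or claim.service_start > end:
            continue
        for category in config.complication_categories:
            if claim.has_code(category.codeset):
                any_pos.add(category.label)
                if category.codeset.matches(claim.primary_dx):
                    primary.add(category.label)
    return bool(any_pos), frozenset(primary), frozenset(any_pos)


def build_episodes(
    member_claims: Sequence[Claim],
    config: StudyConfig,
    window: tuple[datetime.date, datetime.date] | None = None,
) -> list[VOCEpisode]:
    """Construct the chronologically ordered VOC episodes of one patient.

    *member_claims* are all of the patient's claims; VOC-coded claims with a
    service start inside *window* (follow-up, inclusive) seed the episodes,
    while every claim is eligible for the complication scan.
    """
    voc_claims = [c for c in member_claims if c.has_code(config.voc_episode_codes)]
    if window is not None:
        lo, hi = window
        voc_claims = [c for c in voc_claims if lo <= c.service_start <= hi]
    if not voc_claims:
        return []

    episodes = []
    for cluster in _merge_voc_claims(voc_claims, config.episode_gap_days):
        start = min(c.service_start for c in cluster)
        end = max(c.service_end for c in cluster)
        complicated, cat_primary, cat_any = classify_episode(
            start, end, member_claims, config
        )
        episodes.append(
            VOCEpisode(
                patient_id=cluster[0].patient_id,
                start=start,
                end=end,
                claim_ids=tuple(c.claim_id for c in cluster),
                setting=assign_setting(cluster, config.setting_hierarchy),
                complicated=complicated,
                categories_primary=cat_primary,
                categories_any=cat_any,
            )
        )
    return episodes


def extract_episodes(
    members: Sequence[CohortMember],
    claims_map: Mapping[str, Sequence[Claim]],
    config: StudyConfig,
) -> dict[str, list[VOCEpisode]]:
    """Episodes per cohort member, restricted to each member's follow-up."""
    return {
        m.patient_id: build_episodes(
            claims_map.get(m.patient_id, []),
            config,
            window=(m.followup_start, m.followup_end),
        )
        for m in members
    }


@dataclass(frozen=True)
class RateSummary:
    total_episodes: int
    person_years: float
    rate_per_person_year: float
    year1_mean_total: float
    year1_mean_by_setting: dict[str, float]
    year1_count_distribution: dict[str, float]
    fraction_with_episode: float


def episode_rates(
    members: Sequence[CohortMember],
    episodes: Mapping[str, Sequence[VOCEpisode]],
    config: StudyConfig,
) -> RateSummary:
    """Person-year episode rate plus first-year per-patient means.

    An episode belongs to year 1 iff its start lies within the first 365
    days of follow-up.  Person-years are summed follow-up days / 365.25.
    """
    if not members:
        raise ValueError("no cohort members: zero person-time")
    person_years = sum(m.person_years for m in members)
    if person_years <= 0:
        raise ValueError("zero total person-time")

    total = 0
    n_any = 0
    year1_total = 0
    year1_by_setting = {s: 0 for s in config.setting_hierarchy}
    bins = {"0": 0, "1": 0, "2": 0, ">2": 0}
    for m in members:
        eps = episodes.get(m.patient_id, [])
        total += len(eps)
        if eps:
            n_any += 1
        year1 = [
            e for e in eps
            if (e.start - m.followup_start).days < YEAR1_DAYS
        ]
        year1_total += len(year1)
        for e in year1:
            year1_by_setting[e.setting] += 1
        k = len(year1)
        bins["0" if k == 0 else "1" if k == 1 else "2" if k == 2 else ">2"] += 1

    n = len(members)
    return RateSummary(
        total_episodes=total,
        person_years=person_years,
        rate_per_person_year=total / person_years,
        year1_mean_total=year1_total / n,
        year1_mean_by_setting={s: c / n for s, c in year1_by_setting.items()},
        year1_count_distribution={k: v / n for k, v in bins.items()},
        fraction_with_episode=n_any / n,
    )


def write_episodes(
    episodes: Mapping[str, Sequence[VOCEpisode]], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for pid in sorted(episodes):
        for e in episodes[pid]:
            rows.append(
                {
                    "patient_id": e.patient_id,
                    "start": e.start.isoformat(),
                    "end": e.end.isoformat(),
                    "setting": e.setting,
                    "complicated": int(e.complicated),
                    "categories_primary": ";".join(sorted(e.categories_primary)),
                    "categories_any": ";".join(sorted(e.categories_any)),
                    "n_claims": e.n_claims,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "start", "end", "setting", "complicated",
                 "categories_primary", "categories_any", "n_claims"],
    )
    df.to_csv(path, index=False)
    return path
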