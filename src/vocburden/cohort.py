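"""Patient selection and baseline characterization.

Implements the selection cascade (index date in the identification window,
adult age, continuous enrollment with medical + pharmacy benefits over the
baseline and minimum follow-up windows, no clinical-trial code, no dual
eligibility) and the baseline measures (Deyo-adapted Charlson comorbidity
index, ER-visit and inpatient-stay counts, inpatient length of stay).

Conventions (documented, configurable where the source definitions are
ambiguous):

* "6 months" / "12 months" are day counts (183 / 365 by default).
* Age at index is completed years on the index date.
* Inpatient LOS is discharge minus admission in days, with same-day stays
  counted as one day.
* Enrollment spans and claim service intervals are closed day intervals.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codesets import (
    CLAIM_TYPE_TO_SETTING,
    SETTING_TO_CLAIM_TYPE,
    CodeSet,
    ConfigError,
    StudyConfig,
    normalize_code,
)

__all__ = [
    "Claim",
    "EnrollmentSpan",
    "Patient",
    "CohortMember",
    "ExclusionRecord",
    "EXCLUSION_REASONS",
    "find_index_date",
    "is_continuously_enrolled",
    "select_cohort",
    "charlson_score",
    "baseline_utilization",
    "merge_stays",
    "read_patients",
    "read_enrollment",
    "read_claims",
    "write_cohort",
    "write_exclusions",
    "claims_by_patient",
    "spans_by_patient",
]

ONE_DAY = datetime.timedelta(days=1)

EXCLUSION_REASONS = (
    "no_scd_claim_in_window",
    "under_age",
    "insufficient_baseline",
    "insufficient_followup",
    "trial_code",
    "dual_eligible",
)


@dataclass(frozen=True)
class Claim:
    """One service record.  ``dx[0]`` is the primary diagnosis."""

    claim_id: str
    patient_id: str
    service_start: datetime.date
    service_end: datetime.date
    place_of_service: str
    dx: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.service_start > self.service_end:
            raise ValueError(
                f"claim {self.claim_id}: service_start after service_end"
            )
        if not self.dx:
            raise ValueError(f"claim {self.claim_id}: empty diagnosis list")
        object.__setattr__(self, "dx", tuple(normalize_code(c) for c in self.dx))

    @property
    def claim_type(self) -> str:
        return SETTING_TO_CLAIM_TYPE[self.place_of_service]

    @property
    def primary_dx(self) -> str:
        return self.dx[0]

    def has_code(self, codeset: CodeSet, primary_only: bool = False) -> bool:
        positions = self.dx[:1] if primary_only else self.dx
        return any(codeset.matches(c) for c in positions)


@dataclass(frozen=True)
class EnrollmentSpan:
    patient_id: str
    start: datetime.date
    end: datetime.date
    medical: bool
    pharmacy: bool
    dual_eligible: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"enrollment span for {self.patient_id}: start after end")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: datetime.date
    sex: str
    race: str
    region: str


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    index_date: datetime.date
    baseline_start: datetime.date
    followup_start: datetime.date
    followup_end: datetime.date
    age_at_index: int
    sex: str
    race: str
    region: str
    cci: int
    baseline_er_visits: int
    baseline_ip_stays: int
    baseline_ip_los_days: int

    @property
    def followup_days(self) -> int:
        return (self.followup_end - self.followup_start).days

    @property
    def person_years(self) -> float:
        return self.followup_days / 365.25


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    excluded_reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded_reason!r}")


# --- selection primitives -------------------------------------------------

def find_index_date(claims: Sequence[Claim], config: StudyConfig) -> datetime.date | None:
    """Earliest service start of an SCD-coded claim (any dx position)
    inside the identification window; ``None`` if there is no such claim."""
    lo, hi = config.identification_window
    candidates = [
        c.service_start
        for c in claims
        if lo <= c.service_start <= hi and c.has_code(config.scd_codes)
    ]
    return min(candidates) if candidates else None


def _merged_benefit_spans(
    spans: Iterable[EnrollmentSpan],
) -> list[tuple[datetime.date, datetime.date]]:
    """Union of medical+pharmacy spans; abutting spans (end d, start d+1)
    are merged into one interval."""
    eligible = sorted(
        ((s.start, s.end) for s in spans if s.medical and s.pharmacy),
        key=lambda t: t,
    )
    merged: list[tuple[datetime.date, datetime.date]] = []
    for start, end in eligible:
        if merged and start <= merged[-1][1] + ONE_DAY:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def is_continuously_enrolled(
    spans: Iterable[EnrollmentSpan],
    interval: tuple[datetime.date, datetime.date],
) -> bool:
    """True iff every day of the closed *interval* is covered by spans
    carrying both medical and pharmacy benefits."""
    lo, hi = interval
    if lo > hi:
        raise ValueError("interval start after end")
    for start, end in _merged_benefit_spans(spans):
        if start <= lo <= end:
            return hi <= end
    return False


def _covering_span_end(
    spans: Iterable[EnrollmentSpan], day: datetime.date
) -> datetime.date | None:
    for start, end in _merged_benefit_spans(spans):
        if start <= day <= end:
            return end
    return None


def _age_on(birth_date: datetime.date, on: datetime.date) -> int:
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


# --- baseline measures ----------------------------------------------------

# Deyo ICD-9 adaptation of the Charlson comorbidity index: 17 condition
# categories matched on dot-less code prefixes.  Hierarchy rules: complicated
# diabetes supersedes uncomplicated; metastatic disease supersedes any
# malignancy; moderate/severe liver disease supersedes mild.
_DEYO_CATEGORIES: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("myocardial_infarction", 1, ("410", "412")),
    ("congestive_heart_failure", 1, ("428",)),
    ("peripheral_vascular_disease", 1, ("4439", "441", "7854", "V434")),
    ("cerebrovascular_disease", 1, tuple(str(c) for c in range(430, 439))),
    ("dementia", 1, ("290",)),
    ("chronic_pulmonary_disease", 1, (*[str(c) for c in range(490, 497)],
                                      *[str(c) for c in range(500, 506)], "5064")),
    ("rheumatologic_disease", 1, ("7100", "7101", "7104", "7140", "7141",
                                  "7142", "71481", "725")),
    ("peptic_ulcer_disease", 1, ("531", "532", "533", "534")),
    ("mild_liver_disease", 1, ("5712", "5714", "5715", "5716")),
    ("diabetes", 1, ("2500", "2501", "2502", "2503", "2507")),
    ("diabetes_with_complications", 2, ("2504", "2505", "2506")),
    ("hemiplegia_paraplegia", 2, ("342", "3441")),
    ("renal_disease", 2, ("582", "5830", "5831", "5832", "5833", "5834",
                          "5835", "5836", "5837", "585", "586", "588")),
    ("any_malignancy", 2, (*[str(c) for c in range(140, 173)],
                           *[str(c) for c in range(174, 196)],
                           *[str(c) for c in range(200, 209)])),
    ("moderate_severe_liver_disease", 3, ("4560", "4561", "4562",
                                          "5722", "5723", "5724", "5728")),
    ("metastatic_solid_tumor", 6, ("196", "197", "198", "199")),
    ("aids", 6, ("042", "043", "044")),
)

_DEYO_SUPERSEDES = {
    "diabetes_with_complications": "diabetes",
    "metastatic_solid_tumor": "any_malignancy",
    "moderate_severe_liver_disease": "mild_liver_disease",
}


def charlson_score(claims: Sequence[Claim]) -> int:
    """Deyo-adapted Charlson comorbidity index over the given claims.

    Each of the 17 condition categories counts at most once; hierarchy rules
    drop the milder member of each superseding pair.
    """
    codes = {code for claim in claims for code in claim.dx}
    present: set[str] = set()
    for name, _weight, prefixes in _DEYO_CATEGORIES:
        if any(code.startswith(p) for code in codes for p in prefixes):
            present.add(name)
    for severe, mild in _DEYO_SUPERSEDES.items():
        if severe in present:
            present.discard(mild)
    weights = {name: w for name, w, _ in _DEYO_CATEGORIES}
    return sum(weights[name] for name in present)


def merge_stays(
    ip_claims: Sequence[Claim],
) -> list[tuple[datetime.date, datetime.date, list[Claim]]]:
    """Merge overlapping or abutting inpatient claims into stays.

    Returns (admission, discharge, member claims) per stay, chronologically.
    Claims starting no later than one day after the running discharge extend
    the current stay.
    """
    ordered = sorted(ip_claims, key=lambda c: (c.service_start, c.service_end, c.claim_id))
    stays: list[tuple[datetime.date, datetime.date, list[Claim]]] = []
    for claim in ordered:
        if stays and claim.service_start <= stays[-1][1] + ONE_DAY:
            admit, discharge, members = stays[-1]
            members.append(claim)
            stays[-1] = (admit, max(discharge, claim.service_end), members)
        else:
            stays.append((claim.service_start, claim.service_end, [claim]))
    return stays


def stay_los_days(admit: datetime.date, discharge: datetime.date) -> int:
    """Discharge minus admission in days; same-day stays count as 1."""
    return max(1, (discharge - admit).days)


def baseline_utilization(claims: Sequence[Claim]) -> tuple[int, int, int]:
    """(ER visits, inpatient stays, total inpatient LOS days) for one
    patient's baseline claims.

    One ER visit per patient per calendar day; inpatient stays are maximal
    overlapping/abutting runs of inpatient claims.
    """
    er_days = {c.service_start for c in claims if c.place_of_service == "ER"}
    stays = merge_stays([c for c in claims if c.place_of_service == "inpatient"])
    los = sum(stay_los_days(admit, discharge) for admit, discharge, _ in stays)
    return len(er_days), len(stays), los


# --- cohort selection -----------------------------------------------------

def select_cohort(
    patients: Sequence[Patient],
    enrollment: Sequence[EnrollmentSpan],
    claims: Sequence[Claim],
    config: StudyConfig,
) -> tuple[list[CohortMember], list[ExclusionRecord]]:
    """Apply the selection cascade; every input patient lands in exactly one
    of the two output lists.  Exclusion reason is the first rule violated, in
    the order: SCD claim, age, baseline enrollment, follow-up enrollment,
    trial code, dual eligibility.
    """
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id in patients table: {dupes}")

    claims_map = claims_by_patient(claims)
    spans_map = spans_by_patient(enrollment)

    members: list[CohortMember] = []
    exclusions: list[ExclusionRecord] = []
    for patient in patients:
        pid = patient.patient_id
        pclaims = claims_map.get(pid, [])
        pspans = spans_map.get(pid, [])

        index_date = find_index_date(pclaims, config)
        if index_date is None:
            exclusions.append(ExclusionRecord(pid, "no_scd_claim_in_window"))
            continue

        age = _age_on(patient.birth_date, index_date)
        if age < config.min_age:
            exclusions.append(
                ExclusionRecord(pid, "under_age", f"age {age} at index")
            )
            continue

        baseline_start = index_date - datetime.timedelta(days=config.baseline_days)
        baseline_end = index_date - ONE_DAY
        if not is_continuously_enrolled(pspans, (baseline_start, baseline_end)):
            exclusions.append(
                ExclusionRecord(pid, "insufficient_baseline",
                                f"baseline {baseline_start}..{baseline_end}")
            )
            continue

        followup_req_end = index_date + datetime.timedelta(
            days=config.followup_min_days - 1
        )
        if followup_req_end > config.study_end or not is_continuously_enrolled(
            pspans, (index_date, followup_req_end)
        ):
            exclusions.append(
                ExclusionRecord(pid, "insufficient_followup",
                                f"requires coverage through {followup_req_end}")
            )
            continue

        trial = [
            c for c in pclaims
            if config.study_start <= c.service_start <= config.study_end
            and c.has_code(config.trial_exclusion_codes)
        ]
        if trial:
            exclusions.append(
                ExclusionRecord(pid, "trial_code",
                                f"claim {trial[0].claim_id} on {trial[0].service_start}")
            )
            continue

        if any(s.dual_eligible for s in pspans):
            exclusions.append(ExclusionRecord(pid, "dual_eligible"))
            continue

        enroll_end = _covering_span_end(pspans, index_date)
        assert enroll_end is not None  # guaranteed by the follow-up check
        followup_end = min(enroll_end, config.study_end)

        baseline_claims = [
            c for c in pclaims
            if baseline_start <= c.service_start <= baseline_end
        ]
        er_visits, ip_stays, ip_los = baseline_utilization(baseline_claims)
        members.append(
            CohortMember(
                patient_id=pid,
                index_date=index_date,
                baseline_start=baseline_start,
                followup_start=index_date,
                followup_end=followup_end,
                age_at_index=age,
                sex=patient.sex,
                race=patient.race,
                region=patient.region,
                cci=charlson_score(baseline_claims),
                baseline_er_visits=er_visits,
                baseline_ip_stays=ip_stays,
                baseline_ip_los_days=ip_los,
            )
        )
    return members, exclusions


# --- table I/O ------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_patients(path: str | Path) -> list[Patient]:
    df = _read_csv(path)
    return [
        Patient(
            patient_id=row.patient_id,
            birth_date=datetime.date.fromisoformat(row.birth_date),
            sex=row.sex,
            race=row.race,
            region=row.region,
        )
        for row in df.itertuples()
    ]


def read_enrollment(path: str | Path) -> list[EnrollmentSpan]:
    df = _read_csv(path)
    return [
        EnrollmentSpan(
            patient_id=row.patient_id,
            start=datetime.date.fromisoformat(row.span_start),
            end=datetime.date.fromisoformat(row.span_end),
            medical=row.medical == "1",
            pharmacy=row.pharmacy == "1",
            dual_eligible=row.dual_eligible == "1",
        )
        for row in df.itertuples()
    ]


def read_claims(path: str | Path) -> list[Claim]:
    df = _read_csv(path)
    dx_cols = sorted(
        (c for c in df.columns if c.startswith("dx")),
        key=lambda c: int(c[2:]),
    )
    claims = []
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        dx = tuple(rowd[c] for c in dx_cols if rowd[c])
        claims.append(
            Claim(
                claim_id=rowd["claim_id"],
                patient_id=rowd["patient_id"],
                service_start=datetime.date.fromisoformat(rowd["service_start"]),
                service_end=datetime.date.fromisoformat(rowd["service_end"]),
                place_of_service=CLAIM_TYPE_TO_SETTING[rowd["claim_type"]]
                if rowd.get("place_of_service", "") == ""
                else rowd["place_of_service"],
                dx=dx,
            )
        )
    return claims


def claims_by_patient(claims: Iterable[Claim]) -> dict[str, list[Claim]]:
    out: dict[str, list[Claim]] = {}
    for claim in claims:
        out.setdefault(claim.patient_id, []).append(claim)
    for group in out.values():
        group.sort(key=lambda c: (c.service_start, c.service_end, c.claim_id))
    return out


def spans_by_patient(spans: Iterable[EnrollmentSpan]) -> dict[str, list[EnrollmentSpan]]:
    out: dict[str, list[EnrollmentSpan]] = {}
    for span in spans:
        out.setdefault(span.patient_id, []).append(span)
    for group in out.values():
        group.sort(key=lambda s: (s.start, s.end))
    return out


def write_cohort(members: Sequence[CohortMember], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "index_date": m.index_date.isoformat(),
                "baseline_start": m.baseline_start.isoformat(),
                "followup_start": m.followup_start.isoformat(),
                "followup_end": m.followup_end.isoformat(),
                "age_at_index": m.age_at_index,
                "sex": m.sex,
                "race": m.race,
                "region": m.region,
                "cci": m.cci,
                "baseline_er_visits": m.baseline_er_visits,
                "baseline_ip_stays": m.baseline_ip_stays,
                "baseline_ip_los_days": m.baseline_ip_los_days,
            }
            for m in members
        ],
        columns=[
            "patient_id", "index_date", "baseline_start", "followup_start",
            "followup_end", "age_at_index", "sex", "race", "region", "cci",
            "baseline_er_visits", "baseline_ip_stays", "baseline_ip_los_days",
        ],
    )
    df.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> list[CohortMember]:
    df = _read_csv(path)
    return [
        CohortMember(
            patient_id=row.patient_id,
            index_date=datetime.date.fromisoformat(row.index_date),
            baseline_start=datetime.date.fromisoformat(row.baseline_start),
            followup_start=datetime.date.fromisoformat(row.followup_start),
            followup_end=datetime.date.fromisoformat(row.followup_end),
            age_at_index=int(row.age_at_index),
            sex=row.sex,
            race=row.race,
            region=row.region,
            cci=int(row.cci),
            baseline_er_visits=int(row.baseline_er_visits),
            baseline_ip_stays=int(row.baseline_ip_stays),
            baseline_ip_los_days=int(row.baseline_ip_los_days),
        )
        for row in df.itertuples()
    ]


def write_exclusions(exclusions: Sequence[ExclusionRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"patient_id": e.patient_id, "excluded_reason": e.excluded_reason,
             "detail": e.detail}
            for e in exclusions
        ],
        columns=["patient_id", "excluded_reason", "detail"],
    )
    df.to_csv(path, index=False)
    return path
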