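"""Synthetic Medicaid-like claims generator with known ground truth.

Every downstream stage of the pipeline has a recoverable target here:

* patient-level VOC event counts are gamma-mixed Poisson (negative
  binomial), so zero-inflation and overdispersion are reproduced;
* each true episode is materialized as one anchor claim spanning the whole
  episode interval plus optional extra claims inside it, so the greedy gap
  merge recovers the true episode partition exactly;
* consecutive true episodes are separated by strictly more than the merge
  gap, so recovery is well-defined for any seed;
* the anchor claim's place of service equals the true setting and extra
  claims never outrank it in the hierarchy;
* eligibility violations (age, enrollment gap, trial code, dual
  eligibility) are injected at configured probabilities and recorded with
  reasons.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .codesets import SETTINGS, SETTING_TO_CLAIM_TYPE, StudyConfig

__all__ = [
    "SimParams",
    "Demographics",
    "TrueEpisode",
    "PatientTruth",
    "GroundTruth",
    "SimResult",
    "simulate",
    "write_tables",
    "load_params",
]

ONE_DAY = datetime.timedelta(days=1)

# Innocuous filler diagnoses: match none of the default SCD/VOC/complication/
# trial/Charlson code sets.
_FILLER_DX = "78079"
_BASELINE_ER_DX = "7802"
# Baseline comorbidity pool (three Charlson weight-1 codes, one weight-2).
_COMORBIDITY_DX = ("4280", "49390", "25000", "5853")

_FIG3_SETTING_MEANS = (1.06, 0.90, 0.51, 0.24, 0.09)


def _default_setting_probs() -> dict[str, float]:
    total = sum(_FIG3_SETTING_MEANS)
    return {s: m / total for s, m in zip(SETTINGS, _FIG3_SETTING_MEANS)}


@dataclass(frozen=True)
class Demographics:
    """Marginal sampling spec for age group, sex, race, and region."""

    age_groups: tuple[tuple[int, int, float], ...] = (
        (18, 30, 0.519),
        (31, 45, 0.296),
        (46, 64, 0.179),
        (65, 80, 0.006),
    )
    sex_probs: tuple[tuple[str, float], ...] = (("F", 0.673), ("M", 0.327))
    race_probs: tuple[tuple[str, float], ...] = (
        ("Black", 0.740),
        ("White", 0.063),
        ("Hispanic", 0.101),
        ("Other", 0.029),
        ("Unknown", 0.067),
    )
    region_probs: tuple[tuple[str, float], ...] = (
        ("Northeast", 0.446),
        ("North Central", 0.099),
        ("South", 0.266),
        ("West", 0.189),
    )

    def __post_init__(self) -> None:
        for name, probs in (
            ("age_groups", [p for _, _, p in self.age_groups]),
            ("sex_probs", [p for _, p in self.sex_probs]),
            ("race_probs", [p for _, p in self.race_probs]),
            ("region_probs", [p for _, p in self.region_probs]),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"demographics.{name} probabilities must sum to 1")


_DIST_KINDS = ("lognormal", "poisson_plus_one", "constant")


def _check_dist(spec: dict, name: str) -> dict:
    if not isinstance(spec, dict) or spec.get("dist") not in _DIST_KINDS:
        raise ValueError(
            f"{name}: expected a dict with 'dist' in {_DIST_KINDS}, got {spec!r}"
        )
    return dict(spec)


def _sample_positive_int(rng: np.random.Generator, spec: dict) -> int:
    kind = spec["dist"]
    if kind == "lognormal":
        value = rng.lognormal(mean=spec["mu"], sigma=spec["sigma"])
        return int(min(max(1, round(value)), spec.get("cap", 60)))
    if kind == "poisson_plus_one":
        return 1 + int(rng.poisson(spec["lam"]))
    if kind == "constant":
        return int(spec["value"])
    raise AssertionError(kind)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic claims process."""

    n_patients: int = 100
    voc_rate_mean: float = 3.31  # episodes per person-year
    voc_rate_dispersion: float = 0.45  # gamma shape of rate heterogeneity
    setting_probs: dict[str, float] = field(default_factory=_default_setting_probs)
    p_complicated: float = 0.297
    category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "infectious and parasitic diseases": 0.30,
            "fever": 0.22,
            "pulmonary disorders": 0.18,
            "cerebrovascular conditions": 0.12,
            "thrombosis/DVT": 0.10,
            "aseptic (avascular) bone necrosis": 0.08,
        }
    )
    p_complication_primary: float = 0.5  # complicated episode anchored on a complication dx1
    episode_duration_days: dict = field(
        default_factory=lambda: {"dist": "lognormal", "mu": 0.9, "sigma": 0.7, "cap": 30}
    )
    claims_per_episode: dict = field(
        default_factory=lambda: {"dist": "poisson_plus_one", "lam": 0.8}
    )
    inpatient_los_days: dict = field(
        default_factory=lambda: {"dist": "lognormal", "mu": 1.4, "sigma": 0.8, "cap": 60}
    )
    p_trial_code: float = 0.0
    p_dual_eligible: float = 0.0
    p_enrollment_gap: float = 0.0
    p_under_age: float = 0.0
    baseline_er_mean: float = 2.3
    baseline_er_dispersion: float = 0.3
    baseline_ip_mean: float = 0.45
    baseline_ip_dispersion: float = 0.3
    p_baseline_comorbidity: float = 0.3
    demographics: Demographics = field(default_factory=Demographics)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.voc_rate_mean < 0:
            raise ValueError("voc_rate_mean must be >= 0")
        if self.voc_rate_dispersion <= 0:
            raise ValueError("voc_rate_dispersion must be > 0")
        if not self.setting_probs:
            raise ValueError("setting_probs must be non-empty")
        if set(self.setting_probs) != set(SETTINGS):
            raise ValueError(f"setting_probs must cover exactly {SETTINGS}")
        for name in ("setting_probs", "category_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        for name in ("p_complicated", "p_complication_primary", "p_trial_code",
                     "p_dual_eligible", "p_enrollment_gap", "p_under_age",
                     "p_baseline_comorbidity"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for name in ("episode_duration_days", "claims_per_episode",
                     "inpatient_los_days"):
            object.__setattr__(self, name, _check_dist(getattr(self, name), name))

    def expected_primary_voc_share(self) -> float:
        """Expected fraction of SCD-related visits with a VOC primary dx."""
        return 1.0 - self.p_complicated * self.p_complication_primary


@dataclass(frozen=True)
class TrueEpisode:
    start: datetime.date
    end: datetime.date
    setting: str
    complicated: bool
    category: str | None


@dataclass
class PatientTruth:
    patient_id: str
    rate: float  # true per-person-year VOC rate
    exposure_years: float
    episodes: list[TrueEpisode]
    eligible: bool
    reason: str | None


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth]

    def episode_counts(self) -> dict[str, int]:
        return {pid: len(t.episodes) for pid, t in self.patients.items()}

    def eligible_ids(self) -> set[str]:
        return {pid for pid, t in self.patients.items() if t.eligible}

    def to_dict(self) -> dict:
        return {
            pid: {
                "rate": t.rate,
                "exposure_years": t.exposure_years,
                "eligible": t.eligible,
                "reason": t.reason,
                "episodes": [
                    {
                        "start": e.start.isoformat(),
                        "end": e.end.isoformat(),
                        "setting": e.setting,
                        "complicated": e.complicated,
                        "category": e.category,
                    }
                    for e in t.episodes
                ],
            }
            for pid, t in self.patients.items()
        }


@dataclass
class SimResult:
    patients: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    truth: GroundTruth


def _sample_categorical(rng: np.random.Generator, pairs: Sequence[tuple]) -> object:
    labels = [p[0] for p in pairs]
    probs = np.array([p[-1] for p in pairs], dtype=float)
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _birth_date_for_age(
    rng: np.random.Generator, index_date: datetime.date, age: int
) -> datetime.date:
    try:
        anniversary = index_date.replace(year=index_date.year - age)
    except ValueError:  # Feb 29 on a non-leap birth year
        anniversary = index_date.replace(year=index_date.year - age, day=28)
    return anniversary - datetime.timedelta(days=int(rng.integers(0, 365)))


def _gamma_poisson(
    rng: np.random.Generator, mean: float, shape: float, exposure: float = 1.0
) -> tuple[float, int]:
    """Draw a patient rate from Gamma(shape, mean/shape) and a count from
    Poisson(rate * exposure)."""
    if mean == 0:
        return 0.0, 0
    rate = float(rng.gamma(shape, mean / shape))
    return rate, int(rng.poisson(rate * exposure))


def simulate(params: SimParams, config: StudyConfig) -> SimResult:
    """Generate patients, enrollment spans, claims, and the ground truth."""
    rng = np.random.default_rng(params.seed)

    voc_codes = sorted(config.voc_episode_codes.codes)
    index_dx_pool = sorted(config.scd_codes.codes - config.voc_episode_codes.codes)
    index_dx = index_dx_pool[0] if index_dx_pool else voc_codes[0]
    trial_dx = config.trial_exclusion_codes.example_code()
    category_code = {
        c.label: c.codeset.example_code() for c in config.complication_categories
    }
    for label in params.category_probs:
        if label not in category_code:
            raise ValueError(
                f"category_probs references {label!r}, absent from the study config"
            )
    cat_labels = sorted(params.category_probs)
    cat_p = np.array([params.category_probs[c] for c in cat_labels])
    cat_p = cat_p / cat_p.sum()
    setting_labels = list(SETTINGS)
    setting_p = np.array([params.setting_probs[s] for s in setting_labels])
    setting_p = setting_p / setting_p.sum()

    index_lo = max(
        config.identification_window[0],
        config.study_start + datetime.timedelta(days=config.baseline_days),
    )
    index_hi = min(
        config.identification_window[1],
        config.study_end - datetime.timedelta(days=config.followup_min_days - 1),
    )
    if index_lo > index_hi:
        raise ValueError("study windows leave no feasible index dates")
    index_span = (index_hi - index_lo).days + 1

    gap_days = config.episode_gap_days
    patient_rows: list[dict] = []
    enrollment_rows: list[dict] = []
    claim_rows: list[dict] = []
    truth: dict[str, PatientTruth] = {}
    claim_counter = 0

    def add_claim(
        pid: str,
        start: datetime.date,
        end: datetime.date,
        place: str,
        dx: Sequence[str],
    ) -> None:
        nonlocal claim_counter
        claim_counter += 1
        row = {
            "claim_id": f"C{claim_counter:08d}",
            "patient_id": pid,
            "service_start": start.isoformat(),
            "service_end": end.isoformat(),
            "place_of_service": place,
            "claim_type": SETTING_TO_CLAIM_TYPE[place],
            "dx1": dx[0],
            "dx2": dx[1] if len(dx) > 1 else "",
        }
        claim_rows.append(row)

    for i in range(params.n_patients):
        pid = f"P{i + 1:06d}"

        index_date = index_lo + datetime.timedelta(days=int(rng.integers(0, index_span)))

        under_age = rng.random() < params.p_under_age
        if under_age:
            age = int(rng.integers(10, 18))
        else:
            groups = params.demographics.age_groups
            group_p = np.array([p for _, _, p in groups])
            lo, hi, _ = groups[int(rng.choice(len(groups), p=group_p / group_p.sum()))]
            age = int(rng.integers(lo, hi + 1))
        birth_date = _birth_date_for_age(rng, index_date, age)
        sex = _sample_categorical(rng, params.demographics.sex_probs)
        race = _sample_categorical(rng, params.demographics.race_probs)
        region = _sample_categorical(rng, params.demographics.region_probs)
        patient_rows.append(
            {
                "patient_id": pid,
                "birth_date": birth_date.isoformat(),
                "sex": sex,
                "race": race,
                "region": region,
            }
        )

        # --- enrollment, with optional coverage gap -----------------------
        dual = rng.random() < params.p_dual_eligible
        gap_location: str | None = None
        if rng.random() < params.p_enrollment_gap:
            gap_location = "baseline" if rng.random() < 0.5 else "followup"
        if gap_location == "baseline":
            gap_start = index_date - datetime.timedelta(days=90)
            gap_end = gap_start + datetime.timedelta(days=13)
        elif gap_location == "followup":
            gap_start = index_date + datetime.timedelta(days=100)
            gap_end = gap_start + datetime.timedelta(days=13)
        if gap_location is None:
            spans = [(config.study_start, config.study_end)]
        else:
            spans = [
                (config.study_start, gap_start - ONE_DAY),
                (gap_end + ONE_DAY, config.study_end),
            ]
        for span_start, span_end in spans:
            enrollment_rows.append(
                {
                    "patient_id": pid,
                    "span_start": span_start.isoformat(),
                    "span_end": span_end.isoformat(),
                    "medical": "1",
                    "pharmacy": "1",
                    "dual_eligible": "1" if dual else "0",
                }
            )

        # continuous post-index coverage ends at the injected gap, if any
        if gap_location == "followup":
            coverage_end = gap_start - ONE_DAY
        else:
            coverage_end = config.study_end
        followup_end = min(coverage_end, config.study_end)
        exposure_days = (followup_end - index_date).days
        exposure_years = exposure_days / 365.25

        # --- index claim --------------------------------------------------
        add_claim(pid, index_date, index_date, "office", (index_dx,))

        # --- trial-code claim --------------------------------------------
        trial = rng.random() < params.p_trial_code
        if trial:
            offset = int(rng.integers(0, max(1, min(200, exposure_days + 1))))
            day = index_date + datetime.timedelta(days=offset)
            add_claim(pid, day, day, "office", (trial_dx, _FILLER_DX))

        # --- baseline utilization and comorbidity claims ------------------
        baseline_start = index_date - datetime.timedelta(days=config.baseline_days)
        _, n_er = _gamma_poisson(
            rng, params.baseline_er_mean, params.baseline_er_dispersion
        )
        for day_offset in sorted(
            rng.choice(config.baseline_days, size=min(n_er, config.baseline_days),
                       replace=False)
        ):
            day = baseline_start + datetime.timedelta(days=int(day_offset))
            add_claim(pid, day, day, "ER", (_BASELINE_ER_DX,))
        _, n_ip = _gamma_poisson(
            rng, params.baseline_ip_mean, params.baseline_ip_dispersion
        )
        for _ in range(n_ip):
            admit = baseline_start + datetime.timedelta(
                days=int(rng.integers(0, config.baseline_days))
            )
            los = _sample_positive_int(rng, params.inpatient_los_days)
            discharge = min(admit + datetime.timedelta(days=los), index_date - ONE_DAY)
            discharge = max(discharge, admit)
            add_claim(pid, admit, discharge, "inpatient", (_BASELINE_ER_DX,))
        if rng.random() < params.p_baseline_comorbidity:
            day = baseline_start + datetime.timedelta(
                days=int(rng.integers(0, config.baseline_days))
            )
            code = _COMORBIDITY_DX[int(rng.integers(0, len(_COMORBIDITY_DX)))]
            add_claim(pid, day, day, "office", (code,))

        # --- VOC episode process -----------------------------------------
        rate, n_events = _gamma_poisson(
            rng, params.voc_rate_mean, params.voc_rate_dispersion, exposure_years
        )
        durations = [
            _sample_positive_int(rng, params.episode_duration_days)
            for _ in range(n_events)
        ]
        available = exposure_days + 1
        while durations and sum(durations) + (len(durations) - 1) * (gap_days + 1) > available:
            durations.pop()  # truncate rare overfull draws; truth records reality
        n_eps = len(durations)

        episodes: list[TrueEpisode] = []
        if n_eps:
            required = sum(durations) + (n_eps - 1) * (gap_days + 1)
            slack = available - required
            extra = rng.multinomial(slack, np.full(n_eps + 1, 1.0 / (n_eps + 1)))
            cursor = index_date + datetime.timedelta(days=int(extra[0]))
            for j, dur in enumerate(durations):
                start = cursor
                end = start + datetime.timedelta(days=dur - 1)
                setting = setting_labels[int(rng.choice(len(setting_labels), p=setting_p))]
                complicated = rng.random() < params.p_complicated
                category = (
                    cat_labels[int(rng.choice(len(cat_labels), p=cat_p))]
                    if complicated
                    else None
                )
                episodes.append(TrueEpisode(start, end, setting, complicated, category))

                # anchor claim spans the full episode interval
                voc_dx = voc_codes[int(rng.integers(0, len(voc_codes)))]
                if complicated and rng.random() < params.p_complication_primary:
                    anchor_dx: tuple[str, ...] = (category_code[category], voc_dx)
                else:
                    anchor_dx = (voc_dx,)
                add_claim(pid, start, end, setting, anchor_dx)

                # extra claims inside the interval, never outranking the anchor
                priority = setting_labels.index(setting)
                lower = setting_labels[priority:]
                n_extra = _sample_positive_int(rng, params.claims_per_episode) - 1
                for _ in range(n_extra):
                    day = start + datetime.timedelta(days=int(rng.integers(0, dur)))
                    place = lower[int(rng.integers(0, len(lower)))]
                    if place == "ER" and setting == "ER":
                        day = start  # same-day grouping keeps one ER visit
                    extra_voc = voc_codes[int(rng.integers(0, len(voc_codes)))]
                    add_claim(pid, day, day, place, (extra_voc,))

                # dedicated complication claim strictly inside the episode
                if complicated:
                    day = start + datetime.timedelta(days=int(rng.integers(0, dur)))
                    code = category_code[category]
                    dx = (code, _FILLER_DX) if rng.random() < 0.5 else (_FILLER_DX, code)
                    add_claim(pid, day, day, "outpatient", dx)

                cursor = end + datetime.timedelta(days=gap_days + 1 + int(extra[j + 1]))

        # --- eligibility ground truth ------------------------------------
        reason: str | None = None
        if under_age:
            reason = "under_age"
        elif gap_location == "baseline":
            reason = "insufficient_baseline"
        elif gap_location == "followup":
            reason = "insufficient_followup"
        elif trial:
            reason = "trial_code"
        elif dual:
            reason = "dual_eligible"
        truth[pid] = PatientTruth(
            patient_id=pid,
            rate=rate,
            exposure_years=exposure_years,
            episodes=episodes,
            eligible=reason is None,
            reason=reason,
        )

    patients_df = pd.DataFrame(
        patient_rows, columns=["patient_id", "birth_date", "sex", "race", "region"]
    )
    enrollment_df = pd.DataFrame(
        enrollment_rows,
        columns=["patient_id", "span_start", "span_end", "medical", "pharmacy",
                 "dual_eligible"],
    )
    claims_df = pd.DataFrame(
        claim_rows,
        columns=["claim_id", "patient_id", "service_start", "service_end",
                 "place_of_service", "claim_type", "dx1", "dx2"],
    )
    return SimResult(patients_df, enrollment_df, claims_df, GroundTruth(truth))


def write_tables(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write patients/enrollment/claims CSVs plus the ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "enrollment": out / "enrollment.csv",
        "claims": out / "claims.csv",
        "truth": out / "truth.json",
    }
    result.patients.to_csv(paths["patients"], index=False)
    result.enrollment.to_csv(paths["enrollment"], index=False)
    result.claims.to_csv(paths["claims"], index=False)
    paths["truth"].write_text(
        json.dumps(result.truth.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return paths


def load_params(path: str | Path) -> SimParams:
    """Load simulation parameters from a YAML/JSON file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"params file {path} must contain a mapping")
    if "demographics" in raw:
        demo = raw["demographics"]
        raw["demographics"] = Demographics(
            **{
                key: tuple(tuple(entry) for entry in value)
                for key, value in demo.items()
            }
        )
    known = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
    return SimParams(**raw)
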