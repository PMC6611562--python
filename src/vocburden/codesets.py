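"""Diagnosis code sets and study configuration.

All clinical definitions (ICD-9-CM code sets, date windows, the episode gap
threshold, the place-of-service hierarchy) live here as data.  Algorithms in
the other modules receive a :class:`StudyConfig` and never hard-code a
clinical constant.

Codes are stored dot-less internally ("282.42" -> "28242"); every reader
accepts either dialect.  The bundled complication-category mapping is an
*illustrative* default — real studies must supply an authoritative list via
the config file.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ConfigError",
    "DxCode",
    "CodeSet",
    "ComplicationCategory",
    "StudyConfig",
    "SETTINGS",
    "CLAIM_TYPES",
    "SETTING_TO_CLAIM_TYPE",
    "normalize_code",
    "code_matches",
    "load_config",
    "default_config",
]


class ConfigError(ValueError):
    """Raised when a configuration file or value violates an invariant."""


#: Place-of-service labels, in default hierarchy (priority) order.
SETTINGS: tuple[str, ...] = ("inpatient", "ER", "outpatient", "office", "other")

#: Claim-type abbreviations used in the claims table.
CLAIM_TYPES: tuple[str, ...] = ("IP", "ER", "OP", "OFF", "OTH")

SETTING_TO_CLAIM_TYPE: dict[str, str] = dict(zip(SETTINGS, CLAIM_TYPES))
CLAIM_TYPE_TO_SETTING: dict[str, str] = dict(zip(CLAIM_TYPES, SETTINGS))

_ICD9_SHAPE = re.compile(r"^(?:\d{3,5}|[VE]\d{2,4})$")


def normalize_code(code: str) -> str:
    """Return *code* upper-cased with dots stripped; validate ICD-9-CM shape.

    >>> normalize_code("282.42")
    '28242'
    >>> normalize_code("v70.7")
    'V707'
    """
    if not isinstance(code, str) or not code.strip():
        raise ConfigError(f"empty or non-string diagnosis code: {code!r}")
    norm = code.strip().upper().replace(".", "")
    if not _ICD9_SHAPE.match(norm):
        raise ConfigError(f"code {code!r} does not look like an ICD-9-CM code")
    return norm


@dataclass(frozen=True)
class DxCode:
    """A single ICD-9-CM diagnosis code, stored dot-less."""

    value: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", normalize_code(self.value))

    def __eq__(self, other: object) -> bool:  # dot-insensitive identity
        if isinstance(other, DxCode):
            return self.value == other.value
        if isinstance(other, str):
            return self.value == normalize_code(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.value)


@dataclass(frozen=True)
class CodeSet:
    """A named set of diagnosis codes with an exact or prefix match mode."""

    name: str
    codes: frozenset[str]
    match_mode: str = "exact"

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "prefix"):
            raise ConfigError(
                f"code set {self.name!r}: match_mode must be 'exact' or "
                f"'prefix', got {self.match_mode!r}"
            )
        if not self.codes:
            raise ConfigError(f"code set {self.name!r} is empty")
        object.__setattr__(
            self, "codes", frozenset(normalize_code(c) for c in self.codes)
        )

    @classmethod
    def of(cls, name: str, values: Iterable[str], match_mode: str = "exact") -> "CodeSet":
        return cls(name=name, codes=frozenset(values), match_mode=match_mode)

    def matches(self, code: str) -> bool:
        norm = normalize_code(code)
        if norm in self.codes:
            return True
        if self.match_mode == "prefix":
            return any(norm.startswith(c) for c in self.codes)
        return False

    def example_code(self) -> str:
        """A deterministic representative member (used by the simulator)."""
        return min(self.codes)


def code_matches(code: str, codeset: CodeSet) -> bool:
    """True iff *code* (dotted or dot-less) belongs to *codeset*."""
    return codeset.matches(code)


@dataclass(frozen=True)
class ComplicationCategory:
    label: str
    codeset: CodeSet


def _expand_range(stem: str, lo: int, hi: int) -> list[str]:
    return [f"{stem}{i}" for i in range(lo, hi + 1)]


# --- defaults -------------------------------------------------------------

DEFAULT_SCD_CODES = ("28241", "28242", *_expand_range("2826", 0, 9))
DEFAULT_VOC_EPISODE_CODES = ("28242", "28262", "28264", "28269")
DEFAULT_VOC_PRIMARY_REASON_CODES = DEFAULT_SCD_CODES
DEFAULT_TRIAL_EXCLUSION_CODES = ("V707",)

# Illustrative mapping of the six named complication categories to ICD-9
# chapter/category stems.  NOT an authoritative clinical list.
DEFAULT_COMPLICATION_CATEGORIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("infectious and parasitic diseases", ("038", "041", "079", "112", "590")),
    ("fever", ("7806",)),
    ("pulmonary disorders", ("480", "486", "5173", "41511", "51881")),
    ("cerebrovascular conditions", ("430", "431", "433", "434", "435", "436", "437", "438")),
    ("thrombosis/DVT", ("453",)),
    ("aseptic (avascular) bone necrosis", ("7334",)),
)


def _default_categories() -> list[ComplicationCategory]:
    return [
        ComplicationCategory(label, CodeSet.of(label, codes, "prefix"))
        for label, codes in DEFAULT_COMPLICATION_CATEGORIES
    ]


@dataclass(frozen=True)
class StudyConfig:
    """All tunable study parameters: code sets, windows, thresholds."""

    scd_codes: CodeSet = field(
        default_factory=lambda: CodeSet.of("scd", DEFAULT_SCD_CODES)
    )
    voc_episode_codes: CodeSet = field(
        default_factory=lambda: CodeSet.of("voc_episode", DEFAULT_VOC_EPISODE_CODES)
    )
    voc_primary_reason_codes: CodeSet = field(
        default_factory=lambda: CodeSet.of(
            "voc_primary_reason", DEFAULT_VOC_PRIMARY_REASON_CODES
        )
    )
    complication_categories: tuple[ComplicationCategory, ...] = field(
        default_factory=lambda: tuple(_default_categories())
    )
    trial_exclusion_codes: CodeSet = field(
        default_factory=lambda: CodeSet.of("trial", DEFAULT_TRIAL_EXCLUSION_CODES)
    )
    study_start: datetime.date = datetime.date(2009, 1, 1)
    study_end: datetime.date = datetime.date(2013, 12, 31)
    identification_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2009, 7, 1),
        datetime.date(2012, 12, 31),
    )
    baseline_days: int = 183
    followup_min_days: int = 365
    episode_gap_days: int = 3
    setting_hierarchy: tuple[str, ...] = SETTINGS
    min_age: int = 18
    rng_seed: int = 0

    def __post_init__(self) -> None:
        id_start, id_end = self.identification_window
        if not (self.study_start <= id_start <= id_end <= self.study_end):
            raise ConfigError(
                "identification_window must lie within [study_start, study_end]"
            )
        if self.baseline_days <= 0:
            raise ConfigError("baseline_days must be > 0")
        if self.followup_min_days <= 0:
            raise ConfigError("followup_min_days must be > 0")
        if self.episode_gap_days < 0:
            raise ConfigError("episode_gap_days must be >= 0")
        hierarchy = tuple(self.setting_hierarchy)
        if len(set(hierarchy)) != len(hierarchy):
            raise ConfigError("setting_hierarchy entries must be unique")
        missing = set(SETTINGS) - set(hierarchy)
        if missing:
            raise ConfigError(
                f"setting_hierarchy must cover every place of service; "
                f"missing {sorted(missing)}"
            )
        object.__setattr__(self, "setting_hierarchy", hierarchy)
        labels = [c.label for c in self.complication_categories]
        if len(set(labels)) != len(labels):
            raise ConfigError("complication category labels must be unique")
        object.__setattr__(
            self, "complication_categories", tuple(self.complication_categories)
        )

    # -- helpers -----------------------------------------------------------

    def setting_priority(self, setting: str) -> int:
        try:
            return self.setting_hierarchy.index(setting)
        except ValueError:
            raise ConfigError(f"place of service {setting!r} not in hierarchy")

    def category_labels(self) -> list[str]:
        return [c.label for c in self.complication_categories]

    def to_dict(self) -> dict:
        """JSON-serializable view (used for provenance hashing)."""

        def codeset(cs: CodeSet) -> dict:
            return {"match_mode": cs.match_mode, "codes": sorted(cs.codes)}

        return {
            "scd_codes": codeset(self.scd_codes),
            "voc_episode_codes": codeset(self.voc_episode_codes),
            "voc_primary_reason_codes": codeset(self.voc_primary_reason_codes),
            "complication_categories": [
                {"label": c.label, **codeset(c.codeset)}
                for c in self.complication_categories
            ],
            "trial_exclusion_codes": codeset(self.trial_exclusion_codes),
            "study_start": self.study_start.isoformat(),
            "study_end": self.study_end.isoformat(),
            "identification_window": [
                d.isoformat() for d in self.identification_window
            ],
            "baseline_days": self.baseline_days,
            "followup_min_days": self.followup_min_days,
            "episode_gap_days": self.episode_gap_days,
            "setting_hierarchy": list(self.setting_hierarchy),
            "min_age": self.min_age,
            "rng_seed": self.rng_seed,
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config() -> StudyConfig:
    return StudyConfig()


# --- config file loading --------------------------------------------------

def _parse_date(value, key: str) -> datetime.date:
    if isinstance(value, datetime.date) and not isinstance(value, datetime.datetime):
        return value
    if isinstance(value, datetime.datetime):
        return value.date()
    if isinstance(value, str):
        try:
            return datetime.date.fromisoformat(value)
        except ValueError:
            pass
    raise ConfigError(f"key {key!r}: expected an ISO date, got {value!r}")


def _parse_codeset(value, key: str) -> CodeSet:
    if isinstance(value, (list, tuple)):
        return CodeSet.of(key, [str(v) for v in value])
    if isinstance(value, dict):
        codes = value.get("codes")
        if not isinstance(codes, (list, tuple)):
            raise ConfigError(f"key {key!r}: 'codes' must be a list")
        return CodeSet.of(key, [str(c) for c in codes], value.get("match_mode", "exact"))
    raise ConfigError(f"key {key!r}: expected a list of codes or a mapping")


def _parse_categories(value) -> list[ComplicationCategory]:
    key = "complication_categories"
    cats: list[ComplicationCategory] = []
    if isinstance(value, dict):
        value = [{"label": k, "codes": v} for k, v in value.items()]
    if not isinstance(value, (list, tuple)):
        raise ConfigError(f"key {key!r}: expected a list or mapping")
    for entry in value:
        if not isinstance(entry, dict) or "label" not in entry:
            raise ConfigError(f"key {key!r}: each entry needs a 'label'")
        label = str(entry["label"])
        codes = entry.get("codes")
        if not isinstance(codes, (list, tuple)):
            raise ConfigError(f"key {key!r}: category {label!r} needs 'codes'")
        mode = entry.get("match_mode", "prefix")
        cats.append(ComplicationCategory(label, CodeSet.of(label, [str(c) for c in codes], mode)))
    return cats


_SCALAR_INT_KEYS = (
    "baseline_days",
    "followup_min_days",
    "episode_gap_days",
    "min_age",
    "rng_seed",
)
_CODESET_KEYS = (
    "scd_codes",
    "voc_episode_codes",
    "voc_primary_reason_codes",
    "trial_exclusion_codes",
)
_KNOWN_KEYS = set(_SCALAR_INT_KEYS) | set(_CODESET_KEYS) | {
    "complication_categories",
    "study_start",
    "study_end",
    "identification_window",
    "setting_hierarchy",
}


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML/JSON study configuration, supplying defaults for
    every omitted field.  An empty file yields the default study definition.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")

    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key in _CODESET_KEYS:
        if key in raw:
            kwargs[key] = _parse_codeset(raw[key], key)
    if "complication_categories" in raw:
        kwargs["complication_categories"] = tuple(
            _parse_categories(raw["complication_categories"])
        )
    for key in ("study_start", "study_end"):
        if key in raw:
            kwargs[key] = _parse_date(raw[key], key)
    if "identification_window" in raw:
        win = raw["identification_window"]
        if not (isinstance(win, (list, tuple)) and len(win) == 2):
            raise ConfigError("key 'identification_window': expected [start, end]")
        kwargs["identification_window"] = (
            _parse_date(win[0], "identification_window[0]"),
            _parse_date(win[1], "identification_window[1]"),
        )
    if "setting_hierarchy" in raw:
        hier = raw["setting_hierarchy"]
        if not isinstance(hier, (list, tuple)):
            raise ConfigError("key 'setting_hierarchy': expected a list")
        kwargs["setting_hierarchy"] = tuple(str(s) for s in hier)
    for key in _SCALAR_INT_KEYS:
        if key in raw:
            value = raw[key]
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"key {key!r}: expected an integer, got {value!r}")
            kwargs[key] = value

    return StudyConfig(**kwargs)
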