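"""Assessment data model and CSV round-tripping.

One :class:`AssessmentRecord` holds the raw interRAI-style item codes for a
single person on a single assessment date.  Item coding follows the home-care
convention: ADL self-performance 0 (independent) to 6 (total dependence) with
8 meaning "activity did not occur"; decision making 0-4; IADL difficulty 0-2.
The declared value set for every item lives in the bundled data dictionary
(``data/data_dictionary.yaml``), which also drives CSV validation.

Clinical items are optional at the model level (missing cells parse to
``None``); whether a record with missing classifier inputs may be scored is
decided downstream by the missing policy (``reject`` | ``impute_independent``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import date
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import FormatError, RecordValidationError

ADL_ITEMS = (
    "bathing",
    "personal_hygiene",
    "dressing_upper",
    "dressing_lower",
    "walking_indoors",
    "walking_outdoors",
    "locomotion",
    "toilet_use",
    "eating",
    "bed_mobility",
)
IADL_ITEMS = ("meal_preparation", "ordinary_housework", "phone_use")
SETTINGS = ("community", "retirement_home", "supportive_housing", "assisted_living")

#: Items the scale calculators and the reference classifier may read.
CLINICAL_ITEMS = ADL_ITEMS + IADL_ITEMS + (
    "decision_making",
    "short_term_memory_ok",
    "making_self_understood",
    "bladder_incontinence",
    "bowel_incontinence",
    "unstable_conditions",
    "caregiver_distress",
)

CSV_COLUMNS = (
    "person_id",
    "assessment_date",
    *ADL_ITEMS,
    "decision_making",
    "short_term_memory_ok",
    "making_self_understood",
    *IADL_ITEMS,
    "bladder_incontinence",
    "bowel_incontinence",
    "unstable_conditions",
    "caregiver_distress",
    "estimated_aide_minutes",
    "estimated_homemaking_minutes",
    "age",
    "sex",
    "living_alone",
    "setting",
    "on_waitlist_or_hold",
)


@lru_cache(maxsize=1)
def data_dictionary() -> dict:
    """The bundled machine-readable item dictionary."""
    text = resources.files("psakit.data").joinpath("data_dictionary.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def _code_values() -> dict[str, frozenset[int]]:
    out = {}
    for name, spec in data_dictionary()["fields"].items():
        if spec.get("kind") == "code":
            out[name] = frozenset(spec["values"])
    return out


def effective_code(code: int) -> int:
    """ADL code with 8 ("did not occur") recoded to maximal dependence (6)."""
    return 6 if code == 8 else code


class AssessmentRecord(BaseModel):
    """Raw item codes for one person; invalid codes are rejected on construction."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    person_id: str
    assessment_date: date
    bathing: Optional[int] = None
    personal_hygiene: Optional[int] = None
    dressing_upper: Optional[int] = None
    dressing_lower: Optional[int] = None
    walking_indoors: Optional[int] = None
    walking_outdoors: Optional[int] = None
    locomotion: Optional[int] = None
    toilet_use: Optional[int] = None
    eating: Optional[int] = None
    bed_mobility: Optional[int] = None
    decision_making: Optional[int] = None
    short_term_memory_ok: Optional[int] = None
    making_self_understood: Optional[int] = None
    meal_preparation: Optional[int] = None
    ordinary_housework: Optional[int] = None
    phone_use: Optional[int] = None
    bladder_incontinence: Optional[int] = None
    bowel_incontinence: Optional[int] = None
    unstable_conditions: Optional[int] = None
    caregiver_distress: Optional[int] = None
    estimated_aide_minutes: float = 0.0
    estimated_homemaking_minutes: float = 0.0
    age: Optional[float] = None
    sex: Optional[str] = None
    living_alone: Optional[int] = None
    setting: str = "community"
    on_waitlist_or_hold: int = 0

    @field_validator(*CLINICAL_ITEMS)
    @classmethod
    def _check_code(cls, v, info):
        if v is None:
            return v
        allowed = _code_values()[info.field_name]
        if v not in allowed:
            raise ValueError(
                f"{info.field_name} out of range: {v} not in {sorted(allowed)}"
            )
        return v

    @field_validator("estimated_aide_minutes", "estimated_homemaking_minutes")
    @classmethod
    def _check_minutes(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be non-negative, got {v}")
        return v

    @field_validator("setting")
    @classmethod
    def _check_setting(cls, v):
        if v not in SETTINGS:
            raise ValueError(f"setting out of range: {v!r} not in {SETTINGS}")
        return v

    @field_validator("sex")
    @classmethod
    def _check_sex(cls, v):
        if v is not None and v not in ("F", "M", "other"):
            raise ValueError(f"sex out of range: {v!r}")
        return v

    @property
    def adl_items(self) -> dict[str, Optional[int]]:
        return {name: getattr(self, name) for name in ADL_ITEMS}

    @property
    def iadl_difficulty_items(self) -> dict[str, Optional[int]]:
        return {name: getattr(self, name) for name in IADL_ITEMS}

    @classmethod
    def independent(cls, person_id: str = "p1", assessment_date: date | str = date(2013, 6, 1), **overrides) -> "AssessmentRecord":
        """A fully independent baseline record, with optional field overrides.

        Convenience constructor: every clinical item is coded 0 except
        short-term memory, which is coded intact (1).
        """
        base: dict = {name: 0 for name in CLINICAL_ITEMS}
        base["short_term_memory_ok"] = 1
        base.update(
            person_id=person_id,
            assessment_date=assessment_date,
            age=78.0,
            sex="F",
            living_alone=0,
        )
        base.update(overrides)
        return cls(**base)


class ScaleProfile(BaseModel):
    """Deterministic clinical-scale summary of one assessment record."""

    model_config = ConfigDict(extra="forbid")

    self_reliance_impaired: bool
    adl_short: int
    adl_hierarchy: int
    cps: int
    iadl_difficulty: int

    @field_validator("adl_short")
    @classmethod
    def _r16(cls, v):
        if not 0 <= v <= 16:
            raise ValueError(f"adl_short out of range: {v}")
        return v

    @field_validator("adl_hierarchy", "cps", "iadl_difficulty")
    @classmethod
    def _r6(cls, v, info):
        if not 0 <= v <= 6:
            raise ValueError(f"{info.field_name} out of range: {v}")
        return v

    def as_features(self) -> dict[str, int]:
        d = dict(self)
        d["self_reliance_impaired"] = int(self.self_reliance_impaired)
        return d


@dataclass
class ParseIssue:
    """One row-level validation failure."""

    row: int
    message: str


@dataclass
class ParseResult:
    records: list[AssessmentRecord] = field(default_factory=list)
    issues: list[ParseIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


_OPTIONAL_STR = ("sex",)


def _coerce(name: str, raw: str):
    if raw is None or raw == "":
        return None
    if name in ("person_id", "setting") or name in _OPTIONAL_STR:
        return raw
    if name == "assessment_date":
        return date.fromisoformat(raw)
    if name in ("estimated_aide_minutes", "estimated_homemaking_minutes", "age"):
        return float(raw)
    return int(raw)


def parse_assessments(source) -> ParseResult:
    """Read assessment records from a CSV path or open text handle.

    Returns a :class:`ParseResult`; rows failing item validation are collected
    as :class:`ParseIssue` entries rather than raised.  A missing mandatory
    column raises :class:`~psakit.errors.FormatError` naming the column.
    """
    if hasattr(source, "read"):
        return _parse(source)
    with open(source, newline="", encoding="utf-8") as fh:
        return _parse(fh)


def _parse(fh) -> ParseResult:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise FormatError("empty file: no header row")
    missing = [c for c in ("person_id", "assessment_date") if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"missing mandatory column: {missing[0]}")
    unknown = [c for c in reader.fieldnames if c not in CSV_COLUMNS]
    if unknown:
        raise FormatError(f"unknown column: {unknown[0]}")
    result = ParseResult()
    for i, row in enumerate(reader, start=2):
        try:
            payload = {}
            for name, raw in row.items():
                val = _coerce(name, raw)
                if val is not None:
                    payload[name] = val
            result.records.append(AssessmentRecord(**payload))
        except (ValueError, TypeError) as exc:
            result.issues.append(ParseIssue(row=i, message=_first_error(exc)))
    return result


def _first_error(exc) -> str:
    # pydantic wraps field errors; surface the first human-readable message
    if hasattr(exc, "errors"):
        errs = exc.errors()
        if errs:
            e = errs[0]
            msg = e.get("msg", str(exc))
            return msg.removeprefix("Value error, ")
    return str(exc)


def write_assessments(records: Iterable[AssessmentRecord], dest) -> None:
    """Write records as an assessment CSV (round-trips through parse_assessments)."""

    def _write(fh):
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            row = {}
            for name in CSV_COLUMNS:
                v = getattr(rec, name)
                if v is None:
                    row[name] = ""
                elif isinstance(v, date):
                    row[name] = v.isoformat()
                else:
                    row[name] = v
            writer.writerow(row)

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


def records_to_csv_text(records: Iterable[AssessmentRecord]) -> str:
    buf = io.StringIO()
    write_assessments(records, buf)
    return buf.getvalue()


def require_items(record: AssessmentRecord, items: Iterable[str], policy: str = "reject") -> dict[str, int]:
    """Resolve clinical items under the missing policy.

    ``reject`` raises :class:`MissingItemError` naming the first missing item;
    ``impute_independent`` fills the independent code (0, or 1 for
    short_term_memory_ok whose 1 means "memory OK").
    """
    from .errors import MissingItemError

    if policy not in ("reject", "impute_independent"):
        raise RecordValidationError(f"unknown missing policy: {policy!r}")
    out = {}
    for name in items:
        v = getattr(record, name)
        if v is None:
            if policy == "reject":
                raise MissingItemError(f"{record.person_id}: missing item {name}")
            v = 1 if name == "short_term_memory_ok" else 0
        out[name] = v
    return out
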