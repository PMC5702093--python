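"""Dependent-variable construction from billing and assessment data.

The primary dependent variable is the weekly billed hours of personal
support: all services typed ``personal_support`` falling in the 12-week
window after the assessment (half-open, ``assessment_date`` excluded,
``assessment_date + 84 days`` included) are summed and divided by the service
span — the difference in days between first and last visit, floored at one
day for single-visit patients — and multiplied by 7.  The secondary variable
is the assessment-reported estimate: home-health-aide plus homemaking minutes
over the 7-day lookback, converted to hours per week.

Cohort filters mirror the published exclusion rules.  The derivation path
drops hospital-assessed patients, patients receiving case management or
long-term-care placement services only, patients with under three weeks of
active service, and finally patients above the 99th percentile of weekly
billed hours (computed on the cohort remaining after the structural rules).
The guideline path instead drops congregate-living settings, waitlisted
patients with no personal support, and Groups 3-6 patients with no personal
support — and keeps the heaviest users.  Exclusions use first-match
accounting so the ledger totals reconcile exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, RecordValidationError
from .records import AssessmentRecord

WINDOW_DAYS = 84
MIN_ACTIVE_SERVICE_DAYS = 21
SERVICE_TYPES = ("personal_support", "other")
CONGREGATE_SETTINGS = ("retirement_home", "supportive_housing", "assisted_living")


@dataclass(frozen=True)
class ServiceRecord:
    """One billed service event."""

    person_id: str
    service_date: date
    service_type: str
    hours: float

    def __post_init__(self):
        if self.hours < 0:
            raise RecordValidationError(f"hours must be non-negative: {self.hours}")
        if self.service_type not in SERVICE_TYPES:
            raise RecordValidationError(f"unknown service_type: {self.service_type!r}")


@dataclass
class HoursSummary:
    """Weekly-hours summary for one person."""

    weekly_billed_hours: float
    service_days_span: int
    n_visits: int
    span_guard_applied: bool = False
    weekly_estimated_hours: Optional[float] = None


def weekly_billed_hours(
    services: Iterable[ServiceRecord], assessment_date: date
) -> HoursSummary:
    """Weekly billed personal-support hours in the 12-week post-assessment window.

    Only ``personal_support`` services with
    ``assessment_date < service_date <= assessment_date + 84 days`` qualify.
    No qualifying service yields zero hours.  A single qualifying visit has an
    undefined span; it is floored at one day and flagged for review.
    """
    window_end = assessment_date + timedelta(days=WINDOW_DAYS)
    qual = [
        s
        for s in services
        if s.service_type == "personal_support"
        and assessment_date < s.service_date <= window_end
    ]
    if not qual:
        return HoursSummary(0.0, 0, 0)
    dates = [s.service_date for s in qual]
    raw_span = (max(dates) - min(dates)).days
    guard = raw_span < 1
    span = max(1, raw_span)
    total = sum(s.hours for s in qual)
    return HoursSummary(
        weekly_billed_hours=total / span * 7.0,
        service_days_span=span,
        n_visits=len(qual),
        span_guard_applied=guard,
    )


def weekly_estimated_hours(record: AssessmentRecord) -> float:
    """Assessment-reported personal-support hours per week (7-day lookback)."""
    return (record.estimated_aide_minutes + record.estimated_homemaking_minutes) / 60.0


# ---------------------------------------------------------------------------
# vectorised cohort pipeline
# ---------------------------------------------------------------------------

BILLING_COLUMNS = ("person_id", "service_date", "service_type", "hours")


def parse_billing(source) -> pd.DataFrame:
    """Read and validate a billing CSV into a typed DataFrame."""
    df = pd.read_csv(source, dtype={"person_id": str})
    missing = [c for c in BILLING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column: {missing[0]}")
    df["service_date"] = pd.to_datetime(df["service_date"]).dt.date
    if (df["hours"] < 0).any():
        raise RecordValidationError("billing hours must be non-negative")
    bad = set(df["service_type"]) - set(SERVICE_TYPES)
    if bad:
        raise RecordValidationError(f"unknown service_type: {sorted(bad)[0]!r}")
    return df


def billed_hours_frame(
    billing: pd.DataFrame, assessment_dates: pd.DataFrame
) -> pd.DataFrame:
    """Per-person weekly billed hours for a whole cohort.

    ``assessment_dates`` needs columns ``person_id`` and ``assessment_date``;
    the result has one row per person with the same summary fields as
    :func:`weekly_billed_hours` (persons without qualifying services get 0).
    """
    out = assessment_dates[["person_id", "assessment_date"]].copy()
    adate = pd.to_datetime(out["assessment_date"])
    out["assessment_date"] = adate.dt.date
    if len(billing):
        b = billing.merge(
            out.assign(_adate=adate.values), on="person_id", how="inner"
        )
        sdate = pd.to_datetime(b["service_date"])
        in_window = (
            (b["service_type"] == "personal_support")
            & (sdate > b["_adate"])
            & (sdate <= b["_adate"] + pd.Timedelta(days=WINDOW_DAYS))
        )
        b = b[in_window]
        if len(b):
            sdate = pd.to_datetime(b["service_date"])
            agg = (
                b.assign(_sdate=sdate)
                .groupby("person_id")
                .agg(
                    total=("hours", "sum"),
                    first=("_sdate", "min"),
                    last=("_sdate", "max"),
                    n_visits=("hours", "size"),
                )
            )
            raw_span = (agg["last"] - agg["first"]).dt.days
            agg["service_days_span"] = raw_span.clip(lower=1)
            agg["span_guard_applied"] = raw_span < 1
            agg["weekly_billed_hours"] = agg["total"] / agg["service_days_span"] * 7.0
            out = out.merge(
                agg[
                    [
                        "weekly_billed_hours",
                        "service_days_span",
                        "n_visits",
                        "span_guard_applied",
                    ]
                ],
                left_on="person_id",
                right_index=True,
                how="left",
            )
    for col in ("weekly_billed_hours", "service_days_span", "n_visits", "span_guard_applied"):
        if col not in out.columns:
            out[col] = 0
    out["weekly_billed_hours"] = pd.to_numeric(out["weekly_billed_hours"]).fillna(0.0)
    out["n_visits"] = pd.to_numeric(out["n_visits"]).fillna(0).astype(int)
    out["service_days_span"] = pd.to_numeric(out["service_days_span"]).fillna(0).astype(int)
    out["span_guard_applied"] = out["span_guard_applied"].map(lambda v: bool(v) if v == v else False).astype(bool)
    return out


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

def _apply_rules(cohort: pd.DataFrame, rules) -> tuple[pd.DataFrame, dict[str, int]]:
    """First-match exclusion: each row is charged to the first rule it trips."""
    ledger: dict[str, int] = {}
    excluded = pd.Series(False, index=cohort.index)
    for name, mask in rules:
        hit = mask & ~excluded
        ledger[name] = int(hit.sum())
        excluded |= hit
    return cohort[~excluded].copy(), ledger


def _require(cohort: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort missing flag column: {missing[0]}")


def apply_derivation_filters(
    cohort: pd.DataFrame,
    percentile: float = 99.0,
    utilisation_cut: Optional[float] = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Derivation/validation cohort exclusions, structural rules first.

    Expects flag columns ``assessed_in_hospital``,
    ``case_management_or_placement_only``, ``active_service_days`` and the
    computed ``weekly_billed_hours``.  The utilisation cut-off defaults to the
    stated percentile of the cohort remaining after the structural rules (so
    it reflects the analytic population) and is reported in the ledger under
    ``utilisation_cut_hours``; pass ``utilisation_cut`` to reuse a previously
    derived threshold, under which the filter set is idempotent.
    """
    if cohort.empty:
        return cohort.copy(), {}
    _require(
        cohort,
        (
            "assessed_in_hospital",
            "case_management_or_placement_only",
            "active_service_days",
            "weekly_billed_hours",
        ),
    )
    structural = [
        ("assessed_in_hospital", cohort["assessed_in_hospital"].astype(bool)),
        (
            "case_management_or_placement_only",
            cohort["case_management_or_placement_only"].astype(bool),
        ),
        (
            "active_service_under_3_weeks",
            cohort["active_service_days"] < MIN_ACTIVE_SERVICE_DAYS,
        ),
    ]
    kept, ledger = _apply_rules(cohort, structural)
    if len(kept):
        cut = (
            float(np.percentile(kept["weekly_billed_hours"], percentile))
            if utilisation_cut is None
            else float(utilisation_cut)
        )
        over = kept["weekly_billed_hours"] > cut
        ledger[f"above_{percentile:g}th_percentile"] = int(over.sum())
        ledger["utilisation_cut_hours"] = cut
        kept = kept[~over].copy()
    return kept, ledger


def apply_guideline_filters(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Guideline-development exclusions (no utilisation-percentile rule).

    Expects columns ``setting``, ``on_waitlist_or_hold``, ``top_level`` and
    ``weekly_billed_hours``.  Rows with a missing group cannot be assessed by
    the Groups 3-6 rule and are reported under ``unclassified``.
    """
    if cohort.empty:
        return cohort.copy(), {}
    _require(
        cohort,
        ("setting", "on_waitlist_or_hold", "top_level", "weekly_billed_hours"),
    )
    no_ps = cohort["weekly_billed_hours"] <= 0
    top = pd.to_numeric(cohort["top_level"], errors="coerce")
    rules = [
        ("congregate_setting", cohort["setting"].isin(CONGREGATE_SETTINGS)),
        (
            "waitlist_or_hold_no_service",
            cohort["on_waitlist_or_hold"].astype(bool) & no_ps,
        ),
        ("group_3_to_6_no_service", (top >= 3) & no_ps),
    ]
    kept, ledger = _apply_rules(cohort, rules)
    ledger["unclassified"] = int(top.isna().sum())
    return kept, ledger


def write_hours_csv(frame: pd.DataFrame, dest) -> None:
    frame.to_csv(dest, index=False, quoting=csv.QUOTE_MINIMAL)
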