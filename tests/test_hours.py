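"""Weekly-hours construction, window boundaries, and cohort filters."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from psakit.errors import ConfigurationError, RecordValidationError
from psakit.hours import (
    ServiceRecord,
    apply_derivation_filters,
    apply_guideline_filters,
    billed_hours_frame,
    weekly_billed_hours,
    weekly_estimated_hours,
)
from psakit.records import AssessmentRecord

A = date(2013, 6, 1)


def ps(day_offset, hours, person="p", kind="personal_support"):
    return ServiceRecord(person, A + timedelta(days=day_offset), kind, hours)


class TestWeeklyBilled:
    def test_stated_formula(self):
        # 12 h total, first-to-last span 28 days -> 12/28*7 = 3.0
        services = [ps(1, 6.0), ps(29, 6.0)]
        summary = weekly_billed_hours(services, A)
        assert summary.weekly_billed_hours == pytest.approx(3.0)
        assert summary.service_days_span == 28
        assert summary.n_visits == 2
        assert not summary.span_guard_applied

    def test_no_qualifying_visits(self):
        summary = weekly_billed_hours([ps(5, 2.0, kind="other")], A)
        assert summary.weekly_billed_hours == 0.0
        assert summary.n_visits == 0

    def test_single_visit_span_guard(self):
        summary = weekly_billed_hours([ps(10, 2.0)], A)
        assert summary.weekly_billed_hours == pytest.approx(14.0)
        assert summary.span_guard_applied

    def test_window_boundaries_half_open(self):
        # day 84 after assessment is in, day 85 is out, the day itself is out
        assert weekly_billed_hours([ps(84, 2.0)], A).n_visits == 1
        assert weekly_billed_hours([ps(85, 2.0)], A).n_visits == 0
        assert weekly_billed_hours([ps(0, 2.0)], A).n_visits == 0

    def test_negative_hours_rejected(self):
        with pytest.raises(RecordValidationError):
            ServiceRecord("p", A, "personal_support", -1.0)


class TestWeeklyEstimated:
    @pytest.mark.parametrize(
        "aide, homemaking, expected",
        [(120, 60, 3.0), (0, 0, 0.0), (70, 0, 70 / 60)],
    )
    def test_minutes_to_weekly_hours(self, aide, homemaking, expected):
        rec = AssessmentRecord.independent(
            estimated_aide_minutes=aide, estimated_homemaking_minutes=homemaking
        )
        assert weekly_estimated_hours(rec) == pytest.approx(expected)


class TestBilledFrame:
    def test_matches_per_person_function(self, rng):
        rows = []
        expect = {}
        for i in range(40):
            pid = f"p{i}"
            services = [
                ps(int(d), float(h), person=pid)
                for d, h in zip(rng.integers(-10, 100, 6), rng.uniform(0.5, 3, 6))
            ]
            rows.extend(
                {
                    "person_id": s.person_id,
                    "service_date": s.service_date,
                    "service_type": s.service_type,
                    "hours": s.hours,
                }
                for s in services
            )
            expect[pid] = weekly_billed_hours(services, A).weekly_billed_hours
        frame = billed_hours_frame(
            pd.DataFrame(rows),
            pd.DataFrame({"person_id": list(expect), "assessment_date": A}),
        )
        for pid, wh in expect.items():
            got = frame.loc[frame["person_id"] == pid, "weekly_billed_hours"].iloc[0]
            assert got == pytest.approx(wh)


def _derivation_cohort(n=10, **overrides):
    df = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "assessed_in_hospital": 0,
            "case_management_or_placement_only": 0,
            "active_service_days": 84,
            "weekly_billed_hours": np.linspace(1, 5, n),
        }
    )
    for col, vals in overrides.items():
        df[col] = vals
    return df


class TestDerivationFilters:
    def test_hospital_rule(self):
        df = _derivation_cohort(
            10, assessed_in_hospital=[1] + [0] * 9, weekly_billed_hours=2.0
        )
        kept, ledger = apply_derivation_filters(df)
        assert len(kept) == 9
        assert ledger["assessed_in_hospital"] == 1

    def test_percentile_rule_catches_extreme_outlier(self):
        hours = np.concatenate([np.random.default_rng(0).uniform(0, 5, 199), [500.0]])
        df = _derivation_cohort(200, weekly_billed_hours=hours)
        kept, ledger = apply_derivation_filters(df)
        assert ledger["above_99th_percentile"] >= 1
        assert 500.0 not in kept["weekly_billed_hours"].values
        # brute-force percentile: anyone above the sorted 99th percentile is out
        cut = float(np.percentile(hours, 99))
        assert (kept["weekly_billed_hours"] <= cut).all()

    def test_short_service_rule(self):
        df = _derivation_cohort(
            5, active_service_days=[84, 20, 21, 5, 84], weekly_billed_hours=2.0
        )
        kept, ledger = apply_derivation_filters(df)
        assert ledger["active_service_under_3_weeks"] == 2
        assert len(kept) == 3

    def test_empty_cohort(self):
        kept, ledger = apply_derivation_filters(pd.DataFrame())
        assert kept.empty and ledger == {}

    def test_missing_flag_column_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="assessed_in_hospital"):
            apply_derivation_filters(pd.DataFrame({"weekly_billed_hours": [1.0]}))

    def test_ledger_conservation_first_match(self):
        df = _derivation_cohort(
            8,
            assessed_in_hospital=[1, 1, 0, 0, 0, 0, 0, 0],
            case_management_or_placement_only=[1, 0, 1, 0, 0, 0, 0, 0],
            active_service_days=[5, 5, 5, 5, 84, 84, 84, 84],
        )
        kept, ledger = apply_derivation_filters(df)
        counts = {k: v for k, v in ledger.items() if k != "utilisation_cut_hours"}
        assert len(kept) + sum(counts.values()) == len(df)
        # first-match: row 0 counted under hospital only
        assert ledger["assessed_in_hospital"] == 2
        assert ledger["case_management_or_placement_only"] == 1
        assert ledger["active_service_under_3_weeks"] == 1


def _guideline_cohort():
    return pd.DataFrame(
        {
            "person_id": list("abcdef"),
            "setting": ["community", "retirement_home", "community", "community",
                        "community", "community"],
            "on_waitlist_or_hold": [0, 0, 1, 0, 0, 0],
            "top_level": [2, 3, 2, 4, 2, 5],
            "weekly_billed_hours": [0.0, 5.0, 0.0, 0.0, 3.0, 6.0],
        }
    )


class TestGuidelineFilters:
    def test_three_rules(self):
        kept, ledger = apply_guideline_filters(_guideline_cohort())
        # b: retirement home; c: waitlist with no service; d: group 4 with 0 h
        assert set(kept["person_id"]) == {"a", "e", "f"}
        assert ledger["congregate_setting"] == 1
        assert ledger["waitlist_or_hold_no_service"] == 1
        assert ledger["group_3_to_6_no_service"] == 1

    def test_group_two_with_zero_hours_retained(self):
        kept, _ = apply_guideline_filters(_guideline_cohort())
        assert "a" in set(kept["person_id"])  # group 2, 0 h: rule 3 spares it

    def test_no_percentile_exclusion_in_guideline_path(self):
        df = _guideline_cohort()
        df.loc[5, "weekly_billed_hours"] = 1000.0
        kept, _ = apply_guideline_filters(df)
        assert 1000.0 in kept["weekly_billed_hours"].values

    def test_idempotent(self):
        kept, _ = apply_guideline_filters(_guideline_cohort())
        again, ledger2 = apply_guideline_filters(kept)
        assert again.equals(kept)
        assert all(v == 0 for k, v in ledger2.items() if k != "unclassified")


def test_derivation_filters_idempotent_with_derived_cut():
    df = _derivation_cohort(50)
    kept, ledger = apply_derivation_filters(df)
    cut = ledger["utilisation_cut_hours"]
    again, ledger2 = apply_derivation_filters(kept, utilisation_cut=cut)
    assert again.reset_index(drop=True).equals(kept.reset_index(drop=True))
    counts = {k: v for k, v in ledger2.items() if k != "utilisation_cut_hours"}
    assert all(v == 0 for v in counts.values())
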