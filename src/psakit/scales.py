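"""interRAI-style clinical scale calculators.

Five summaries are computed from the raw item codes:

* **Self-Reliance Index (SRI)** — dichotomous screen for cognitive or physical
  impairment: any difficulty in daily decision making (code >= 1), or
  supervision or any physical help (code >= 2, with 8 counting as dependent)
  in bathing, personal hygiene, dressing lower body, walking indoors or
  outdoors, or locomotion.
* **ADL Short scale (0-16)** — sum of four recoded self-performance items
  (personal hygiene, toilet use, locomotion, eating); the recode table
  collapsing 0-6/8 onto 0-4 ships as package data.
* **ADL Hierarchy (0-6)** — early-loss vs late-loss functional hierarchy over
  the same four items; eating is the late-loss anchor.
* **CPS (0-6)** — Cognitive Performance Scale from decision making,
  short-term memory, making self understood, and eating.
* **IADL Difficulty (0-6)** — sum of three 0-2 difficulty codes
  (meal preparation, ordinary housework, phone use).

All calculators are pure functions of the record and respect the configured
missing policy (default ``reject``).
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

from .records import AssessmentRecord, ScaleProfile, effective_code, require_items

ADL_SHORT_ITEMS = ("personal_hygiene", "toilet_use", "locomotion", "eating")
SRI_ADL_ITEMS = (
    "bathing",
    "personal_hygiene",
    "dressing_lower",
    "walking_indoors",
    "walking_outdoors",
    "locomotion",
)

#: Table-style interpretation bands for the scales.
IADL_BANDS = (("Minimal difficulty", 0, 1), ("Moderate difficulty", 2, 4), ("Great difficulty", 5, 6))
CPS_BANDS = (("No impairment", 0, 0), ("Mild impairment", 1, 2), ("Moderate impairment", 3, 4), ("Severe impairment", 5, 6))
ADL_HIERARCHY_BANDS = (("Independent", 0, 0), ("Mostly independent", 1, 2), ("Extensive assistance", 3, 4), ("Mostly dependent", 5, 6))


@lru_cache(maxsize=None)
def _table(name: str) -> dict[int, int]:
    text = resources.files("psakit.data").joinpath(name).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    key, val = rows[0].keys()
    return {int(r[key]): int(r[val]) for r in rows}


def adl_short_recode(code: int) -> int:
    """Recode one 0-6/8 self-performance code onto the 0-4 short-scale metric."""
    return _table("adl_short_recode.csv")[code]


def _hier_cat(code: int) -> int:
    """Need category for the hierarchy: 0 independent/setup, 1 supervision or
    limited assistance, 2 extensive, 3 dependent (codes 6 and 8)."""
    return _table("adl_hierarchy_categories.csv")[code]


def self_reliance_index(record: AssessmentRecord, policy: str = "reject") -> bool:
    """True iff the person triggers the Self-Reliance Index (impaired)."""
    items = require_items(record, ("decision_making", *SRI_ADL_ITEMS), policy)
    if items["decision_making"] >= 1:
        return True
    return any(effective_code(items[k]) >= 2 for k in SRI_ADL_ITEMS)


def adl_short(record: AssessmentRecord, policy: str = "reject") -> int:
    items = require_items(record, ADL_SHORT_ITEMS, policy)
    return sum(adl_short_recode(v) for v in items.values())


def adl_hierarchy(record: AssessmentRecord, policy: str = "reject") -> int:
    items = require_items(record, ADL_SHORT_ITEMS, policy)
    early = [_hier_cat(items[k]) for k in ("personal_hygiene", "toilet_use", "locomotion")]
    late = _hier_cat(items["eating"])
    if late == 3:
        # dependent in eating: total dependence when every early-loss item
        # needs at least extensive assistance
        return 6 if min(early) >= 2 else 5
    if late == 2:
        return 4
    return max(*early, late)


def cps(record: AssessmentRecord, policy: str = "reject") -> int:
    items = require_items(
        record,
        ("decision_making", "short_term_memory_ok", "making_self_understood", "eating"),
        policy,
    )
    d = items["decision_making"]
    memory_problem = items["short_term_memory_ok"] == 0
    u = items["making_self_understood"]
    eat = effective_code(items["eating"])
    if d >= 4:  # severely impaired decision making
        return 6 if eat >= 6 else 5
    impairments = int(d >= 1) + int(memory_problem) + int(u >= 1)
    if impairments == 0:
        return 0
    if impairments == 1:
        return 1
    severe = int(d >= 2) + int(u >= 2)
    return 2 + severe


def iadl_difficulty(record: AssessmentRecord, policy: str = "reject") -> int:
    items = require_items(record, ("meal_preparation", "ordinary_housework", "phone_use"), policy)
    return sum(items.values())


def scale_profile(record: AssessmentRecord, policy: str = "reject") -> ScaleProfile:
    """All five scale values for one record (pure function of the record)."""
    return ScaleProfile(
        self_reliance_impaired=self_reliance_index(record, policy),
        adl_short=adl_short(record, policy),
        adl_hierarchy=adl_hierarchy(record, policy),
        cps=cps(record, policy),
        iadl_difficulty=iadl_difficulty(record, policy),
    )


def band(bands, value: int) -> str:
    """Interpretation band label for a scale value, e.g. band(CPS_BANDS, 2)."""
    for label, lo, hi in bands:
        if lo <= value <= hi:
            return label
    raise ValueError(f"value {value} outside all bands")
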