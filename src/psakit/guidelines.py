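"""Percentile-based allocation guidelines and the statutory-cap validator.

For each need group the empirical 20th/35th/50th/65th/80th percentiles of
weekly billed hours define a banded allocation framework: allocations are
expected around the median (the 35th-65th "typical" band), occasionally in
the 20th-80th "occasional" band, and only exceptionally beyond it.  Band
boundaries are inclusive, so the three zones partition the non-negative hours
axis exactly.  A narrower 45th-55th typical band is available as a
configuration for policies that prefer tighter targets.

The statutory validator enforces the provincial service ceilings: up to 120
hours of personal support in the first 30-day period and up to 90 hours in
any subsequent 30-day period, with exemptions (long-term-care waitlist, end
of life, extraordinary circumstances) suppressing — but logging — the flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RecordValidationError

FIRST_PERIOD_CAP_HOURS = 120.0
SUBSEQUENT_PERIOD_CAP_HOURS = 90.0
EXEMPTIONS = ("ltc_waitlist", "end_of_life", "extraordinary")

BAND_PERCENTILES = (20, 35, 45, 50, 55, 65, 80)


@dataclass
class GuidelineBand:
    """Weekly-hours percentile band for one group."""

    group: str
    p20: float
    p35: float
    p45: float
    p50: float
    p55: float
    p65: float
    p80: float
    n: int

    def __post_init__(self):
        seq = [self.p20, self.p35, self.p45, self.p50, self.p55, self.p65, self.p80]
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ConfigurationError(f"band for group {self.group}: percentiles not monotone")


def build_guidelines(
    cohort: pd.DataFrame,
    group_col: str = "group",
    hours_col: str = "weekly_billed_hours",
    min_n: int = 30,
) -> list[GuidelineBand]:
    """Per-group percentile bands (guideline filters assumed already applied).

    Groups with fewer than ``min_n`` members are suppressed with a warning:
    their percentiles would not be stable enough to guide allocation.
    Quantiles use linear interpolation of the empirical distribution.
    """
    bands = []
    for group, sub in cohort.groupby(group_col, sort=True):
        h = sub[hours_col].to_numpy(dtype=float)
        if len(h) < min_n:
            warnings.warn(f"group {group}: n={len(h)} < {min_n}; band suppressed")
            continue
        ps = np.percentile(h, BAND_PERCENTILES)
        bands.append(GuidelineBand(str(group), *(float(p) for p in ps), n=len(h)))
    return bands


def bands_frame(bands: list[GuidelineBand]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bands])


def allocation_zone(
    group: str, proposed_hours: float, bands: list[GuidelineBand], narrow: bool = False
) -> str:
    """Zone of a proposed allocation: ``typical``, ``occasional`` or ``exceptional``.

    Typical: within the 35th-65th percentile band (45th-55th when
    ``narrow``), inclusive.  Occasional: within the 20th-80th band but
    outside the typical band.  Exceptional: outside the 20th-80th band.
    """
    if proposed_hours < 0:
        raise RecordValidationError("proposed hours must be non-negative")
    by_group = {b.group: b for b in bands}
    if str(group) not in by_group:
        raise ConfigurationError(f"no guideline band for group {group!r}")
    b = by_group[str(group)]
    lo, hi = (b.p45, b.p55) if narrow else (b.p35, b.p65)
    if lo <= proposed_hours <= hi:
        return "typical"
    if b.p20 <= proposed_hours <= b.p80:
        return "occasional"
    return "exceptional"


def statutory_check(allocations, exemptions: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Flag 30-day-period totals exceeding the statutory ceilings.

    ``allocations`` is a DataFrame (or list of dicts) with ``period_index``
    (1-based) and ``hours``; an optional ``exemption`` column naming one of
    ``ltc_waitlist | end_of_life | extraordinary`` suppresses the flag but is
    logged in the ``exemption_applied`` column.  The ceilings are inclusive:
    exactly 120 h in period 1 (or 90 h later) passes.
    """
    df = pd.DataFrame(allocations).copy()
    for col in ("period_index", "hours"):
        if col not in df.columns:
            raise ConfigurationError(f"allocations missing column: {col}")
    if (df["hours"] < 0).any():
        raise RecordValidationError("allocation hours must be non-negative")
    if (df["period_index"] < 1).any():
        raise ConfigurationError("period_index must be 1-based")
    if "exemption" not in df.columns:
        df["exemption"] = None
    bad = set(df["exemption"].dropna()) - set(EXEMPTIONS)
    if bad:
        raise ConfigurationError(f"unknown exemption: {sorted(bad)[0]!r}")
    df["cap_hours"] = np.where(
        df["period_index"] == 1, FIRST_PERIOD_CAP_HOURS, SUBSEQUENT_PERIOD_CAP_HOURS
    )
    over = df["hours"] > df["cap_hours"]
    exempt = df["exemption"].notna()
    df["exemption_applied"] = over & exempt
    df["flagged"] = over & ~exempt
    return df
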