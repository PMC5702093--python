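"""Validation metrics for a case-mix grouping of weekly hours.

Fit of a grouping is judged exactly as in the case-mix literature: predict
every patient with their group mean, then report

* **explained variance** ``1 - SSE/SST`` (the R-squared of regressing hours
  on group indicators),
* **coefficient of variation of the model**, ``100 * RMSE / grand mean``
  where the RMSE is over within-group residuals (a documented
  reconstruction — the conventional relative-closeness measure), and
* the **ratio of the highest to the lowest group mean** (discriminatory
  ability).

Per-group descriptive statistics use the sample standard deviation (ddof=1)
and linear-interpolation ("type 7") quantiles; both choices are fixed so that
published tables are reproducible from raw data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "GroupStats",
    "ModelFit",
    "group_stats",
    "explained_variance",
    "model_cv",
    "group_ratio",
    "model_fit",
    "stratified_fit",
]


@dataclass
class GroupStats:
    """Descriptive weekly-hours statistics for one group."""

    group: str
    n: int
    percent: float
    mean: Optional[float]
    sd: Optional[float]
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    cv: Optional[float]


@dataclass
class ModelFit:
    explained_variance: float
    coefficient_of_variation: float  # percent
    group_ratio: Optional[float]


def group_stats(
    cohort: pd.DataFrame,
    group_col: str = "group",
    hours_col: str = "weekly_billed_hours",
) -> list[GroupStats]:
    """Per-group n, %, mean, sd, median, quartiles and CV (sd/mean)."""
    if group_col not in cohort.columns or hours_col not in cohort.columns:
        raise ConfigurationError(f"cohort needs columns {group_col!r} and {hours_col!r}")
    total = len(cohort)
    out = []
    for group, sub in cohort.groupby(group_col, sort=True):
        h = sub[hours_col].to_numpy(dtype=float)
        n = len(h)
        if n == 0:
            out.append(GroupStats(str(group), 0, 0.0, None, None, None, None, None, None))
            continue
        mean = float(h.mean())
        sd = float(h.std(ddof=1)) if n > 1 else 0.0
        q1, med, q3 = (float(v) for v in np.quantile(h, [0.25, 0.5, 0.75]))
        cv = sd / mean if mean > 0 else None
        out.append(
            GroupStats(
                group=str(group),
                n=n,
                percent=100.0 * n / total,
                mean=mean,
                sd=sd,
                median=med,
                q1=q1,
                q3=q3,
                cv=cv,
            )
        )
    return out


def stats_frame(stats: list[GroupStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats])


def _sse_sst(groups, hours) -> tuple[float, float]:
    df = pd.DataFrame({"g": np.asarray(groups), "h": np.asarray(hours, dtype=float)})
    grand = df["h"].mean()
    sst = float(((df["h"] - grand) ** 2).sum())
    means = df.groupby("g")["h"].transform("mean")
    sse = float(((df["h"] - means) ** 2).sum())
    return sse, sst


def explained_variance(groups, hours) -> float:
    """Proportion of hours variability captured by the group means (R²)."""
    if len(groups) != len(hours):
        raise ConfigurationError("groups and hours must align")
    sse, sst = _sse_sst(groups, hours)
    if sst == 0.0:
        warnings.warn("zero total variance; explained variance defined as 0")
        return 0.0
    return 1.0 - sse / sst


def model_cv(groups, hours) -> float:
    """Coefficient of variation of the model: 100 × within-group RMSE / grand mean."""
    hours = np.asarray(hours, dtype=float)
    grand = hours.mean()
    if grand <= 0:
        raise ConfigurationError("grand mean must be positive for model_cv")
    sse, _ = _sse_sst(groups, hours)
    rmse = math.sqrt(sse / len(hours))
    return 100.0 * rmse / grand


def group_ratio(stats: list[GroupStats]) -> Optional[float]:
    """Highest group mean divided by lowest group mean."""
    means = [s.mean for s in stats if s.mean is not None and s.n > 0]
    if len(means) < 2:
        raise ConfigurationError("need at least two non-empty groups")
    lo, hi = min(means), max(means)
    if lo <= 0:
        warnings.warn("lowest group mean is 0; ratio undefined (inf)")
        return math.inf
    return hi / lo


def model_fit(groups, hours) -> ModelFit:
    df = pd.DataFrame({"group": np.asarray(groups), "h": np.asarray(hours, dtype=float)})
    stats = group_stats(df, "group", "h")
    return ModelFit(
        explained_variance=explained_variance(df["group"], df["h"]),
        coefficient_of_variation=model_cv(df["group"], df["h"]),
        group_ratio=group_ratio(stats),
    )


def stratified_fit(
    cohort: pd.DataFrame,
    stratum_col: str,
    group_col: str = "group",
    hours_col: str = "weekly_billed_hours",
) -> tuple[dict[str, ModelFit], dict[str, tuple[float, float]]]:
    """ModelFit per stratum plus a min-max summary over strata.

    Strata with fewer than two distinct groups are skipped with a warning.
    """
    if stratum_col not in cohort.columns:
        raise ConfigurationError(f"missing stratum column: {stratum_col}")
    fits: dict[str, ModelFit] = {}
    for stratum, sub in cohort.groupby(stratum_col):
        if sub[group_col].nunique() < 2:
            warnings.warn(f"stratum {stratum!r} has < 2 groups; skipped")
            continue
        fits[str(stratum)] = model_fit(sub[group_col], sub[hours_col])
    if not fits:
        return fits, {}
    summary = {
        "explained_variance": (
            min(f.explained_variance for f in fits.values()),
            max(f.explained_variance for f in fits.values()),
        ),
        "coefficient_of_variation": (
            min(f.coefficient_of_variation for f in fits.values()),
            max(f.coefficient_of_variation for f in fits.values()),
        ),
        "group_ratio": (
            min(f.group_ratio for f in fits.values()),
            max(f.group_ratio for f in fits.values()),
        ),
    }
    return fits, summary
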