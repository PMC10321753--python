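"""Survival screen: favorable / unfavorable labels from expression stratification.

Stage 2 of the cascade.  Samples are split either into extreme expression
quartiles (low arm: value <= 25th percentile, high arm: value >= 75th
percentile, middle excluded) or by cohort z-score (high arm: z > cutoff,
default 2.0, against all other samples).  The arms are compared by
Kaplan-Meier / log-rank.  A gene is labeled *unfavorable* when the
high-expression arm has significantly worse survival and *favorable* when
significantly better; direction is decided by restricted-mean survival up to
the shorter arm's last event time, which stays defined under heavy censoring
where medians may not be (medians are still reported).

Quantiles use NumPy's linear-interpolation convention.  Boundary inclusion:
the low arm uses <=, the high arm uses >=.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rank_stats import KMCurve, LogRankResult, km_curve, logrank

__all__ = [
    "quartile_groups",
    "zscore_groups",
    "survival_contrast",
    "SurvivalContrast",
]


def _as_series(values) -> pd.Series:
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if s.isna().any():
        raise ValidationError("expression values contain missing entries")
    return s


def quartile_groups(values, lo: float = 0.25, hi: float = 0.75) -> pd.Series:
    """Assign "low" / "high" to extreme-quartile samples, NA to the middle.

    Raises when fewer than 8 samples, when all values are equal, or when the
    two quantile cuts collide so that a sample would fall in both arms.
    """
    s = _as_series(values)
    if s.size < 8:
        raise ValidationError("quartile stratification requires at least 8 samples")
    v = s.to_numpy()
    if np.all(v == v[0]):
        raise ValidationError("degenerate expression: all values equal")
    ql = float(np.quantile(v, lo))
    qh = float(np.quantile(v, hi))
    low_mask = v <= ql
    high_mask = v >= qh
    if np.any(low_mask & high_mask):
        raise ValidationError(
            f"quantile cuts collide (lo={ql:g}, hi={qh:g}); stratification is degenerate"
        )
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[low_mask] = "low"
    out[high_mask] = "high"
    return out


def zscore_groups(values, cutoff: float = 2.0) -> pd.Series:
    """Split samples into "high" (cohort z-score > cutoff) vs "rest".

    z is computed across the whole cohort with the sample standard deviation
    (ddof=1).  Raises on zero variance or when either arm would be empty.
    """
    s = _as_series(values)
    sd = float(s.std(ddof=1))
    if not math.isfinite(sd) or sd == 0.0:
        raise ValidationError("zero variance: z-scores undefined")
    z = (s - s.mean()) / sd
    high = z > cutoff
    if high.sum() == 0 or high.sum() == s.size:
        raise ValidationError(
            f"degenerate z split at cutoff {cutoff}: {int(high.sum())} of {s.size} high"
        )
    out = pd.Series("rest", index=s.index, dtype=object)
    out[high] = "high"
    return out


@dataclass(frozen=True)
class SurvivalContrast:
    """Outcome of a two-arm expression-stratified survival comparison."""

    rule: str                 # "quartile" or "zscore"
    other_label: str          # "low" or "rest"
    n_high: int
    n_other: int
    logrank: LogRankResult
    curve_high: KMCurve
    curve_other: KMCurve
    median_high: float
    median_other: float
    rmean_high: float
    rmean_other: float
    tau: float
    label: str                # "favorable" / "unfavorable" / "none"


def survival_contrast(groups: pd.Series, clinical: pd.DataFrame, alpha: float = 0.05,
                      rule: str = "quartile") -> SurvivalContrast:
    """Kaplan-Meier / log-rank comparison of a "high" arm against its reference.

    ``groups`` maps sample id to arm label ("high" plus one reference label;
    NA entries are excluded).  ``clinical`` is indexed by sample id with
    columns ``time`` and ``event``.  Label semantics: *unfavorable* = the
    high-expression arm has significantly worse survival (smaller restricted
    mean), *favorable* = significantly better, *none* when p >= alpha.
    """
    arms = groups.dropna()
    labels = sorted(set(arms))
    if "high" not in labels or len(labels) != 2:
        raise ValidationError(f"expected arms 'high' plus one reference, got {labels}")
    other = next(l for l in labels if l != "high")

    missing = arms.index.difference(clinical.index)
    if len(missing):
        raise ValidationError(f"samples missing from clinical table: {list(missing)[:10]}")
    high_ids = arms.index[arms == "high"]
    other_ids = arms.index[arms == other]
    if len(high_ids) == 0 or len(other_ids) == 0:
        raise ValidationError("empty survival arm")

    ids = high_ids.append(other_ids)
    time = clinical.loc[ids, "time"].to_numpy(dtype=float)
    event = clinical.loc[ids, "event"].to_numpy()
    group = np.array(["high"] * len(high_ids) + [other] * len(other_ids))

    lr = logrank(time, event, group)
    ch = km_curve(time[: len(high_ids)], event[: len(high_ids)])
    co = km_curve(time[len(high_ids):], event[len(high_ids):])

    # common horizon for the restricted-mean comparison
    tau = min(float(np.max(time[: len(high_ids)])), float(np.max(time[len(high_ids):])))
    rm_h = ch.restricted_mean(tau)
    rm_o = co.restricted_mean(tau)

    label = "none"
    if lr.p < alpha:
        if rm_h < rm_o:
            label = "unfavorable"
        elif rm_h > rm_o:
            label = "favorable"
    return SurvivalContrast(
        rule=rule,
        other_label=other,
        n_high=len(high_ids),
        n_other=len(other_ids),
        logrank=lr,
        curve_high=ch,
        curve_other=co,
        median_high=ch.median(),
        median_other=co.median(),
        rmean_high=rm_h,
        rmean_other=rm_o,
        tau=tau,
        label=label,
    )
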