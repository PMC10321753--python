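"""IFN-gamma signature index.

The index summarizes how strongly a tumor sample expresses a 10-gene
IFN-gamma response cluster.  For each signature gene the samples are
converted to rank percentiles (average rank / n across the cohort), and the
per-sample index is the mean of those percentiles over the signature genes.
Because it is built purely from ranks, the index is invariant under any
per-gene strictly increasing transform of the expression values, so z-scores,
log-normalized values, or TPM all give the same index.

Samples with an index above the high cut (default 0.75) and below the low
cut (default 0.25) form the extreme strata compared by Kaplan-Meier /
log-rank; the middle band is excluded (strict inequalities at both cuts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rank_stats import KMCurve, LogRankResult, km_curve, logrank, rank_percentile

__all__ = [
    "DEFAULT_SIGNATURE_GENES",
    "SignatureDefinition",
    "compute_index",
    "index_survival_contrast",
    "IndexSurvivalContrast",
]

#: Ten-gene IFN-gamma response cluster.  "HLA-D" is not a single gene symbol;
#: HLA-DRA is used as the default surrogate and is configurable.
DEFAULT_SIGNATURE_GENES = (
    "IFNG",
    "STAT1",
    "CCR5",
    "CXCL9",
    "CXCL10",
    "CXCL11",
    "IDO1",
    "PRF1",
    "GZMA",
    "HLA-DRA",
)


@dataclass(frozen=True)
class SignatureDefinition:
    genes: tuple = DEFAULT_SIGNATURE_GENES

    def __post_init__(self):
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise ValidationError("signature must contain at least one gene")
        if len(set(genes)) != len(genes):
            raise ValidationError("signature genes must be unique")


def as_signature(signature) -> SignatureDefinition:
    if signature is None:
        return SignatureDefinition()
    if isinstance(signature, SignatureDefinition):
        return signature
    return SignatureDefinition(tuple(signature))


def compute_index(expression: pd.DataFrame, signature=None) -> pd.Series:
    """Per-sample IFN-gamma index: mean rank percentile of signature genes.

    Parameters
    ----------
    expression
        Genes x samples matrix (rows indexed by gene identifier).
    signature
        Gene list or :class:`SignatureDefinition`; defaults to the 10-gene
        IFN-gamma cluster.
    """
    sig = as_signature(signature)
    missing = [g for g in sig.genes if g not in expression.index]
    if missing:
        raise ValidationError(f"signature genes missing from expression matrix: {missing}")
    if expression.shape[1] < 3:
        raise ValidationError("need at least 3 samples to compute the index")
    pct = np.vstack(
        [rank_percentile(expression.loc[g].to_numpy(dtype=float)) for g in sig.genes]
    )
    return pd.Series(pct.mean(axis=0), index=expression.columns, name="ifng_index")


@dataclass(frozen=True)
class IndexSurvivalContrast:
    result: LogRankResult
    curve_high: KMCurve
    curve_low: KMCurve
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    high_cut: float
    low_cut: float

    @property
    def high_arm_better(self) -> bool:
        """True when the high-index arm has the larger restricted mean survival."""
        tau = min(
            self.curve_high.event_times[-1] if self.curve_high.event_times.size else math.inf,
            self.curve_low.event_times[-1] if self.curve_low.event_times.size else math.inf,
        )
        if not math.isfinite(tau):
            return False
        return self.curve_high.restricted_mean(tau) > self.curve_low.restricted_mean(tau)


def index_survival_contrast(
    index: pd.Series,
    clinical: pd.DataFrame,
    high_cut: float = 0.75,
    low_cut: float = 0.25,
) -> IndexSurvivalContrast:
    """Compare survival of samples with index > high_cut vs < low_cut.

    ``clinical`` must be indexed by sample id with columns ``time`` and
    ``event`` and must cover every sample in ``index``.  Boundary samples
    (index exactly at a cut) fall in the excluded middle band.
    """
    if not (0.0 <= low_cut < high_cut <= 1.0):
        raise ValidationError("cuts must satisfy 0 <= low_cut < high_cut <= 1")
    missing = index.index.difference(clinical.index)
    if len(missing):
        raise ValidationError(f"samples missing from clinical table: {list(missing)[:10]}")

    high_ids = index.index[index > high_cut]
    low_ids = index.index[index < low_cut]
    if len(high_ids) == 0 or len(low_ids) == 0:
        raise ValidationError(
            f"empty stratum: {len(high_ids)} samples above {high_cut}, "
            f"{len(low_ids)} below {low_cut}"
        )

    ids = high_ids.append(low_ids)
    time = clinical.loc[ids, "time"].to_numpy(dtype=float)
    event = clinical.loc[ids, "event"].to_numpy()
    group = np.array(["high"] * len(high_ids) + ["low"] * len(low_ids))

    lr = logrank(time, event, group)
    ch = km_curve(time[: len(high_ids)], event[: len(high_ids)])
    cl = km_curve(time[len(high_ids):], event[len(high_ids):])
    return IndexSurvivalContrast(
        result=lr,
        curve_high=ch,
        curve_low=cl,
        n_high=len(high_ids),
        n_low=len(low_ids),
        median_high=ch.median(),
        median_low=cl.median(),
        high_cut=high_cut,
        low_cut=low_cut,
    )
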