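"""Correlation screen: classify candidate genes against the IFN-gamma signature.

Stage 1 of the prioritization cascade.  Each candidate gene is correlated
(Spearman) with every signature gene; a candidate is called *positive* when
at least ``k_min`` of the pairs are significant (p < alpha) with rho > 0 and
no pair is significant in the opposite direction, *negative* symmetrically,
and *none* otherwise.  No cross-candidate multiplicity correction is
applied: the screen mirrors a raw-p heatmap read-out.

Pairwise-complete samples are used per pair, so missing values in one gene
do not discard samples for the other pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rank_stats import spearman
from .signature import SignatureDefinition, as_signature

__all__ = ["CorrelationRow", "correlate_vs_signature", "classify_direction", "screen_all"]


@dataclass
class CorrelationRow:
    gene: str
    signature_genes: tuple
    rho: np.ndarray
    p: np.ndarray
    n_used: np.ndarray
    self_pair: np.ndarray
    degenerate: bool
    direction: str = "none"
    n_pos_sig: int = 0
    n_neg_sig: int = 0


def classify_direction(rho, p, alpha: float = 0.05, k_min: int = 5) -> tuple[str, int, int]:
    """Aggregate per-pair correlations into a direction call.

    Returns (direction, n significant positive pairs, n significant negative
    pairs).  Pairs with NaN rho or p (degenerate / incomputable) never count.
    """
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    valid = np.isfinite(rho) & np.isfinite(p)
    pos = int(np.sum(valid & (p < alpha) & (rho > 0)))
    neg = int(np.sum(valid & (p < alpha) & (rho < 0)))
    if pos >= k_min and neg == 0:
        return "positive", pos, neg
    if neg >= k_min and pos == 0:
        return "negative", pos, neg
    return "none", pos, neg


def correlate_vs_signature(
    expression: pd.DataFrame,
    gene: str,
    signature=None,
    alpha: float = 0.05,
    k_min: int = 5,
    p_method: str = "t_approx",
) -> CorrelationRow:
    """One screen row: the candidate gene against every signature gene.

    A candidate that is itself a signature gene is allowed; the self-pair is
    flagged in ``self_pair`` (its rho is 1 by construction).  A constant
    candidate row yields a degenerate row with direction "none" rather than
    an error.
    """
    sig = as_signature(signature)
    if gene not in expression.index:
        raise ValidationError(f"candidate gene not in expression matrix: {gene!r}")
    missing = [g for g in sig.genes if g not in expression.index]
    if missing:
        raise ValidationError(f"signature genes missing from expression matrix: {missing}")

    x = expression.loc[gene].to_numpy(dtype=float)
    k = len(sig.genes)
    rho = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    n_used = np.zeros(k, dtype=int)
    self_pair = np.zeros(k, dtype=bool)
    degenerate = False

    for i, sg in enumerate(sig.genes):
        y = expression.loc[sg].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        n_used[i] = int(mask.sum())
        self_pair[i] = sg == gene
        if n_used[i] < 3:
            degenerate = True
            continue
        try:
            rho[i], pval[i] = spearman(x[mask], y[mask], p_method=p_method)
        except ValueError:
            degenerate = True  # constant on the complete cases

    direction, pos, neg = classify_direction(rho, pval, alpha=alpha, k_min=k_min)
    return CorrelationRow(
        gene=gene,
        signature_genes=sig.genes,
        rho=rho,
        p=pval,
        n_used=n_used,
        self_pair=self_pair,
        degenerate=degenerate,
        direction=direction,
        n_pos_sig=pos,
        n_neg_sig=neg,
    )


def screen_all(
    expression: pd.DataFrame,
    candidates,
    signature=None,
    alpha: float = 0.05,
    k_min: int = 5,
    p_method: str = "t_approx",
) -> pd.DataFrame:
    """Screen every candidate; one row per candidate, in input order.

    Output columns: ``direction``, ``n_pos_sig``, ``n_neg_sig``,
    ``degenerate``, then per signature gene ``rho_<gene>`` and ``p_<gene>``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("candidate list is empty")
    sig = as_signature(signature)
    unknown = [g for g in candidates if g not in expression.index]
    if unknown:
        raise ValidationError(f"unknown candidate gene(s): {unknown[:10]}")

    rows = []
    for gene in candidates:
        row = correlate_vs_signature(
            expression, gene, sig, alpha=alpha, k_min=k_min, p_method=p_method
        )
        rec = {
            "direction": row.direction,
            "n_pos_sig": row.n_pos_sig,
            "n_neg_sig": row.n_neg_sig,
            "degenerate": row.degenerate,
        }
        for i, sg in enumerate(sig.genes):
            rec[f"rho_{sg}"] = row.rho[i]
            rec[f"p_{sg}"] = row.p[i]
        rows.append(rec)
    return pd.DataFrame(rows, index=pd.Index(candidates, name="gene"))
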