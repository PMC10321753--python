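"""Downstream-effector triage.

Given knockout-vs-control differential-expression tables from three
compartments (bulk tumor, sorted tumor cells, cultured cells), the triage

1. filters each table at BH-adjusted p < 0.05 and linear fold change >= 1.5
   (i.e. |log2FC| >= log2 1.5),
2. intersects the per-compartment up and down sets, keeping only genes with
   a consistent direction in all compartments, and
3. re-screens the consistent genes in the bulk cohort: Spearman correlation
   against the IFN-gamma signature and against the candidate nuclear
   receptor, plus a z > 2.0 high-expressor survival split.

A *suppressive effector* is a commonly down-regulated gene (down upon NR
knockout, i.e. positively controlled by the NR) that correlates negatively
with the signature and carries unfavorable survival; an *immune-activating*
gene is the mirror image (commonly up, positive correlation, favorable
survival).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import correlate_vs_signature
from .exceptions import ValidationError
from .rank_stats import bh_adjust, spearman
from .signature import as_signature
from .survival import survival_contrast, zscore_groups

__all__ = ["filter_de", "intersect_consistent", "triage_effectors"]

REQUIRED_DE_COLUMNS = ("gene", "log2fc", "pval")


def filter_de(table: pd.DataFrame, fc_cut: float = 1.5, q_cut: float = 0.05
              ) -> tuple[set, set]:
    """Split one DE table into (up set, down set).

    ``table`` needs columns ``gene``, ``log2fc``, ``pval``; a ``padj`` column
    is used when present and recomputed by Benjamini-Hochberg otherwise.  The
    fold-change threshold is applied on the linear scale: up means
    log2FC >= log2(fc_cut), down means log2FC <= -log2(fc_cut).
    """
    missing = [c for c in REQUIRED_DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table lacks required columns: {missing}")
    if table["gene"].duplicated().any():
        dupes = table["gene"][table["gene"].duplicated()].tolist()
        raise ValidationError(f"DE table has duplicated genes: {dupes[:10]}")
    padj = (
        table["padj"].to_numpy(dtype=float)
        if "padj" in table.columns
        else bh_adjust(table["pval"].to_numpy(dtype=float))
    )
    lfc = table["log2fc"].to_numpy(dtype=float)
    lcut = math.log2(fc_cut)
    sig = padj < q_cut
    genes = table["gene"].to_numpy()
    up = set(genes[sig & (lfc >= lcut)])
    down = set(genes[sig & (lfc <= -lcut)])
    return up, down


def intersect_consistent(filtered: dict) -> tuple[set, set]:
    """Direction-consistent intersection across compartments.

    ``filtered`` maps compartment name to an (up set, down set) pair.  A gene
    is *common up* when it is up in every compartment and down in none
    (symmetrically for *common down*); genes with mixed directions are in
    neither set, so the two outputs are always disjoint.
    """
    if len(filtered) < 2:
        raise ValidationError("need at least two compartments to intersect")
    ups = [set(u) for u, _ in filtered.values()]
    downs = [set(d) for _, d in filtered.values()]
    all_up = set.intersection(*ups)
    all_down = set.intersection(*downs)
    any_up = set.union(*ups)
    any_down = set.union(*downs)
    return all_up - any_down, all_down - any_up


@dataclass(frozen=True)
class EffectorCall:
    gene: str
    regulation: str           # "common_up" or "common_down"
    present: bool             # found in the bulk expression matrix
    corr_direction: str       # direction vs the IFN-gamma signature
    rho_nr: float             # Spearman rho vs the candidate NR
    p_nr: float
    survival_label: str       # from the z > cutoff split
    survival_p: float
    role: str                 # "suppressive_effector" / "immune_activating" / "none"


def triage_effectors(
    common_up,
    common_down,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    candidate_nr: str,
    signature=None,
    alpha: float = 0.05,
    k_min: int = 5,
    z_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Assign final roles to direction-consistent knockout-responsive genes.

    Genes absent from the bulk matrix are flagged (``present=False``) rather
    than fatal.  The correlation against the candidate NR is reported but not
    gated on: the role follows the regulation direction, the signature
    correlation, and the survival label.
    """
    if candidate_nr not in expression.index:
        raise ValidationError(f"candidate NR not in expression matrix: {candidate_nr!r}")
    sig = as_signature(signature)
    nr_values = expression.loc[candidate_nr].to_numpy(dtype=float)

    rows = []
    plan = [(g, "common_up") for g in sorted(common_up)] + \
           [(g, "common_down") for g in sorted(common_down)]
    for gene, regulation in plan:
        if gene not in expression.index:
            rows.append(EffectorCall(gene, regulation, False, "none",
                                     math.nan, math.nan, "none", math.nan, "none"))
            continue
        crow = correlate_vs_signature(expression, gene, sig, alpha=alpha,
                                      k_min=k_min)
        x = expression.loc[gene].to_numpy(dtype=float)
        if gene == candidate_nr:
            rho_nr, p_nr = 1.0, 0.0
        else:
            try:
                rho_nr, p_nr = spearman(x, nr_values)
            except ValueError:
                rho_nr, p_nr = math.nan, math.nan
        try:
            groups = zscore_groups(expression.loc[gene], cutoff=z_cutoff)
            contrast = survival_contrast(groups, clinical, alpha=alpha, rule="zscore")
            surv_label, surv_p = contrast.label, contrast.logrank.p
        except ValidationError:
            surv_label, surv_p = "none", math.nan

        role = "none"
        if regulation == "common_down" and crow.direction == "negative" \
                and surv_label == "unfavorable":
            role = "suppressive_effector"
        elif regulation == "common_up" and crow.direction == "positive" \
                and surv_label == "favorable":
            role = "immune_activating"
        rows.append(EffectorCall(gene, regulation, True, crow.direction,
                                 rho_nr, p_nr, surv_label, surv_p, role))

    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.set_index("gene") if len(df) else df
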