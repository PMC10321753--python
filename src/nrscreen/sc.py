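"""Single-cell screen: tumor-intrinsic expression filter and ICT-response contrast.

Stages 3-4 of the cascade work on annotated single-cell expression
(an :class:`anndata.AnnData` with ``obs`` columns ``cell_type``, ``patient``
and ``response``).  Two read-outs:

* *percent expressing* -- for a gene and cell type, 100 x (cells with
  expression above the detection threshold, default strictly > 0) / (cells of
  that type).  The tumor-intrinsic filter keeps genes whose malignant-cell
  percent strictly exceeds tau (default 10%).
* *response contrast* -- malignant-cell expression pooled per ICT response
  group and compared with the unpaired Wilcoxon rank-sum test; a positive
  difference means higher expression in nonresponders.  Cell-level pooling
  ignores within-patient correlation; a patient-mean variant is available
  via ``level="patient"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rank_stats import wilcoxon_rank_sum

__all__ = [
    "percent_expressing",
    "summarize_expression",
    "malignant_filter",
    "response_contrast",
    "ResponseContrast",
]

RESPONSE_LABELS = ("responder", "nonresponder")


def _gene_column(cells, gene: str) -> np.ndarray:
    if gene not in cells.var_names:
        raise ValidationError(f"gene not in cell matrix: {gene!r}")
    col = cells[:, gene].X
    if hasattr(col, "toarray"):
        col = col.toarray()
    return np.asarray(col, dtype=float).ravel()


def _require_obs(cells, column: str) -> pd.Series:
    if column not in cells.obs.columns:
        raise ValidationError(f"cell annotations lack required column {column!r}")
    return cells.obs[column]


def percent_expressing(cells, gene: str, cell_type: str, threshold: float = 0.0) -> float:
    """Percent of cells of ``cell_type`` with expression > ``threshold``."""
    types = _require_obs(cells, "cell_type")
    mask = (types == cell_type).to_numpy()
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(f"no cells annotated as {cell_type!r}")
    x = _gene_column(cells, gene)[mask]
    return 100.0 * float(np.sum(x > threshold)) / n


def summarize_expression(cells, genes=None, threshold: float = 0.0) -> pd.DataFrame:
    """Tidy per gene x cell type summary.

    Columns: ``gene``, ``cell_type``, ``n_cells``, ``n_expressing``,
    ``percent_expressing``, ``mean_expressing`` (mean among expressing cells,
    NaN when none express).
    """
    genes = list(cells.var_names) if genes is None else list(genes)
    types = _require_obs(cells, "cell_type")
    records = []
    masks = {ct: (types == ct).to_numpy() for ct in pd.unique(types)}
    for gene in genes:
        x = _gene_column(cells, gene)
        for ct, mask in masks.items():
            sub = x[mask]
            expressing = sub > threshold
            n_exp = int(expressing.sum())
            records.append(
                {
                    "gene": gene,
                    "cell_type": ct,
                    "n_cells": int(mask.sum()),
                    "n_expressing": n_exp,
                    "percent_expressing": 100.0 * n_exp / mask.sum(),
                    "mean_expressing": float(sub[expressing].mean()) if n_exp else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)


def malignant_filter(summary: pd.DataFrame, tau: float = 10.0,
                     malignant_label: str = "malignant") -> pd.Series:
    """Per-gene pass/fail: malignant-cell percent expressing strictly > tau."""
    sub = summary[summary["cell_type"] == malignant_label]
    if sub.empty:
        raise ValidationError(f"summary has no rows for cell type {malignant_label!r}")
    return pd.Series(
        (sub["percent_expressing"] > tau).to_numpy(),
        index=pd.Index(sub["gene"], name="gene"),
        name="tumor_intrinsic",
    )


@dataclass(frozen=True)
class ResponseContrast:
    gene: str
    mean_responder: float
    mean_nonresponder: float
    difference: float          # nonresponder - responder; positive = higher in nonresponders
    statistic: float
    p: float
    n_responder: int
    n_nonresponder: int
    level: str


def response_contrast(cells, gene: str, cell_type: str = "malignant",
                      threshold: float = 0.0, level: str = "cell") -> ResponseContrast:
    """Compare malignant-cell expression between ICT responders and nonresponders.

    ``level="cell"`` pools single cells per group (each cell one observation);
    ``level="patient"`` first averages within patient.  Two-sided p from the
    unpaired Wilcoxon rank-sum test.
    """
    del threshold  # the contrast uses the values themselves, not detection calls
    types = _require_obs(cells, "cell_type")
    response = _require_obs(cells, "response")
    mask = (types == cell_type).to_numpy()
    if not mask.any():
        raise ValidationError(f"no cells annotated as {cell_type!r}")
    resp = response.to_numpy()[mask]
    bad = set(pd.unique(resp)) - set(RESPONSE_LABELS)
    if bad:
        raise ValidationError(f"unknown response labels: {sorted(bad)}")
    x = _gene_column(cells, gene)[mask]

    groups = {}
    for lab in RESPONSE_LABELS:
        sel = resp == lab
        if not sel.any():
            raise ValidationError(f"no {cell_type} cells in response group {lab!r}")
        if level == "cell":
            groups[lab] = x[sel]
        elif level == "patient":
            pat = _require_obs(cells, "patient").to_numpy()[mask][sel]
            df = pd.DataFrame({"patient": pat, "x": x[sel]})
            groups[lab] = df.groupby("patient", sort=True)["x"].mean().to_numpy()
        else:
            raise ValidationError(f"unknown pooling level {level!r}")

    stat, p = wilcoxon_rank_sum(groups["nonresponder"], groups["responder"])
    m_r = float(np.mean(groups["responder"]))
    m_n = float(np.mean(groups["nonresponder"]))
    return ResponseContrast(
        gene=gene,
        mean_responder=m_r,
        mean_nonresponder=m_n,
        difference=m_n - m_r,
        statistic=stat,
        p=p,
        n_responder=int(groups["responder"].size),
        n_nonresponder=int(groups["nonresponder"].size),
        level=level,
    )
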