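"""Full prioritization cascade as a model-style object.

:class:`NuclearReceptorScreen` is built from a bulk expression matrix, a
clinical table, and an annotated single-cell matrix; :meth:`fit` executes the
four screening stages for every candidate gene (no early exit, so the funnel
is fully observable) and returns a :class:`ScreenResults` with per-candidate
verdicts, the stage funnel, and a JSON-serializable run report.

Stage order and coherence
-------------------------
1. *signature correlation* -- Spearman screen against the IFN-gamma
   signature; fixes the candidate's orientation (positive / negative).
2. *survival* -- extreme-quartile Kaplan-Meier contrast; must be concordant
   with the orientation (negative orientation -> unfavorable survival,
   positive -> favorable).
3. *ICT response* -- malignant-cell Wilcoxon contrast; negative orientation
   requires higher expression in nonresponders, positive the reverse.
4. *tumor intrinsic* -- expressed in > tau percent of malignant cells.

A candidate passing all four stages with negative orientation is an
*immune-evasion candidate*; with positive orientation a *protective
candidate* (reported separately).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .correlation import screen_all
from .exceptions import ValidationError
from .sc import percent_expressing, response_contrast, summarize_expression
from .signature import as_signature, compute_index, index_survival_contrast
from .survival import quartile_groups, survival_contrast
from .io import read_cells, read_clinical, read_expression

__all__ = ["ScreenConfig", "NuclearReceptorScreen", "ScreenResults", "run_screen"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for every cascade stage (all configurable, all reported)."""

    alpha: float = 0.05          # per-pair and per-test significance level
    k_min: int = 5               # signature pairs required for a direction call
    lo_quantile: float = 0.25    # survival screen low arm
    hi_quantile: float = 0.75    # survival screen high arm
    z_cutoff: float = 2.0        # high-expressor z split (effector triage)
    tau: float = 10.0            # malignant percent-expressing filter (%)
    fc_cut: float = 1.5          # DE linear fold-change cut
    q_cut: float = 0.05          # DE BH-adjusted p cut
    index_high: float = 0.75     # IFN-gamma index strata
    index_low: float = 0.25
    detection_threshold: float = 0.0
    response_level: str = "cell"
    malignant_label: str = "malignant"
    p_method: str = "t_approx"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0,1)")
        if not 0 <= self.lo_quantile < self.hi_quantile <= 1:
            raise ValidationError("quantiles must satisfy 0 <= lo < hi <= 1")
        if not 0 <= self.index_low < self.index_high <= 1:
            raise ValidationError("index cuts must satisfy 0 <= low < high <= 1")
        if self.tau < 0 or self.tau >= 100:
            raise ValidationError("tau must lie in [0, 100)")
        if self.k_min < 1:
            raise ValidationError("k_min must be >= 1")
        if self.fc_cut <= 1 or not 0 < self.q_cut < 1:
            raise ValidationError("fc_cut must exceed 1 and q_cut lie in (0,1)")


class NuclearReceptorScreen:
    """The four-stage candidate-gene screen, statsmodels-style.

    Parameters
    ----------
    expression
        Bulk genes x samples matrix (z-scores or log-normalized values).
    clinical
        Table indexed by sample id with ``time``, ``event`` and optionally
        ``response``.
    cells
        AnnData with ``cell_type`` / ``patient`` / ``response`` annotations.
    candidates
        Genes to screen; defaults to every non-signature gene present in both
        the bulk and the single-cell matrix.
    """

    def __init__(self, expression, clinical, cells, candidates=None,
                 signature=None, config: ScreenConfig | None = None,
                 seed: int | None = None):
        self.config = config or ScreenConfig()
        self.config.validate()
        self.signature = as_signature(signature)
        self.expression = expression
        self.clinical = clinical
        self.cells = cells
        self.seed = seed

        missing_clin = expression.columns.difference(clinical.index)
        if len(missing_clin):
            raise ValidationError(
                f"samples missing from clinical table: {list(missing_clin)[:10]}"
            )
        if candidates is None:
            sig = set(self.signature.genes)
            candidates = [g for g in expression.index
                          if g not in sig and g in set(cells.var_names)]
        candidates = list(candidates)
        if not candidates:
            raise ValidationError("no candidate genes to screen")
        bad_expr = [g for g in candidates if g not in expression.index]
        bad_cells = [g for g in candidates if g not in set(cells.var_names)]
        if bad_expr or bad_cells:
            raise ValidationError(
                f"candidates missing from bulk matrix: {bad_expr[:10]}; "
                f"from cell matrix: {bad_cells[:10]}"
            )
        self.candidates = candidates

    def fit(self) -> "ScreenResults":
        cfg = self.config
        index = compute_index(self.expression, self.signature)
        try:
            idx_contrast = index_survival_contrast(
                index, self.clinical, high_cut=cfg.index_high, low_cut=cfg.index_low
            )
        except ValidationError:
            idx_contrast = None

        corr = screen_all(
            self.expression, self.candidates, self.signature,
            alpha=cfg.alpha, k_min=cfg.k_min, p_method=cfg.p_method,
        )

        rows = []
        for gene in self.candidates:
            direction = corr.loc[gene, "direction"]
            pass_corr = direction in ("positive", "negative")

            surv_label, surv_p = "none", math.nan
            try:
                groups = quartile_groups(
                    self.expression.loc[gene],
                    lo=cfg.lo_quantile, hi=cfg.hi_quantile,
                )
                contrast = survival_contrast(groups, self.clinical,
                                             alpha=cfg.alpha, rule="quartile")
                surv_label, surv_p = contrast.label, contrast.logrank.p
            except ValidationError:
                pass
            surv_coherent = (
                (direction == "negative" and surv_label == "unfavorable")
                or (direction == "positive" and surv_label == "favorable")
            )

            rc = response_contrast(
                self.cells, gene, cell_type=cfg.malignant_label,
                level=cfg.response_level,
            )
            resp_coherent = rc.p < cfg.alpha and (
                (direction == "negative" and rc.difference > 0)
                or (direction == "positive" and rc.difference < 0)
            )

            pct = percent_expressing(
                self.cells, gene, cfg.malignant_label,
                threshold=cfg.detection_threshold,
            )
            tumor_intrinsic = pct > cfg.tau

            pass1 = pass_corr
            pass2 = pass1 and surv_coherent
            pass3 = pass2 and resp_coherent
            pass4 = pass3 and tumor_intrinsic
            if pass4:
                final = ("immune_evasion_candidate" if direction == "negative"
                         else "protective_candidate")
            else:
                final = "none"
            rows.append({
                "gene": gene,
                "direction": direction,
                "survival_label": surv_label,
                "survival_p": surv_p,
                "response_diff": rc.difference,
                "response_p": rc.p,
                "malignant_percent": pct,
                "signature_correlated": pass_corr,
                "survival_concordant": pass2,
                "response_concordant": pass3,
                "tumor_intrinsic_pass": pass4,
                "final_call": final,
            })

        verdicts = pd.DataFrame(rows).set_index("gene")
        funnel = {
            "candidates": len(verdicts),
            "signature_correlated": int(verdicts["signature_correlated"].sum()),
            "survival_concordant": int(verdicts["survival_concordant"].sum()),
            "response_concordant": int(verdicts["response_concordant"].sum()),
            "tumor_intrinsic": int(verdicts["tumor_intrinsic_pass"].sum()),
        }
        report = {
            "package": "nrscreen",
            "version": __version__,
            "seed": self.seed,
            "thresholds": asdict(self.config),
            "signature": list(self.signature.genes),
            "n_samples": int(self.expression.shape[1]),
            "n_cells": int(self.cells.n_obs),
            "funnel": funnel,
            "immune_evasion_candidates": sorted(
                verdicts.index[verdicts["final_call"] == "immune_evasion_candidate"]
            ),
            "protective_candidates": sorted(
                verdicts.index[verdicts["final_call"] == "protective_candidate"]
            ),
        }
        if idx_contrast is not None:
            report["ifng_index_contrast"] = {
                "chi2": idx_contrast.result.chi2,
                "p": idx_contrast.result.p,
                "n_high": idx_contrast.n_high,
                "n_low": idx_contrast.n_low,
                "median_high": idx_contrast.median_high,
                "median_low": idx_contrast.median_low,
            }
        return ScreenResults(
            verdicts=verdicts, funnel=funnel, report=report, index=index,
            index_contrast=idx_contrast, config=self.config,
        )


@dataclass
class ScreenResults:
    """Fitted screen: verdict table, stage funnel, and run report."""

    verdicts: pd.DataFrame
    funnel: dict
    report: dict
    index: pd.Series
    index_contrast: object
    config: ScreenConfig

    def recount_funnel(self) -> dict:
        """Recount the funnel directly from the verdict table (consistency oracle)."""
        v = self.verdicts
        return {
            "candidates": len(v),
            "signature_correlated": int(v["signature_correlated"].sum()),
            "survival_concordant": int(v["survival_concordant"].sum()),
            "response_concordant": int(v["response_concordant"].sum()),
            "tumor_intrinsic": int(v["tumor_intrinsic_pass"].sum()),
        }

    def summary(self) -> str:
        f = self.funnel
        lines = [
            "Nuclear receptor immune-evasion screen",
            "=" * 46,
            f"candidates screened          {f['candidates']:>6}",
            f"signature correlated         {f['signature_correlated']:>6}",
            f"+ survival concordant        {f['survival_concordant']:>6}",
            f"+ ICT response concordant    {f['response_concordant']:>6}",
            f"+ tumor intrinsic (> {self.config.tau:g}%)   {f['tumor_intrinsic']:>6}",
            "-" * 46,
            "immune-evasion candidates: "
            + (", ".join(self.report["immune_evasion_candidates"]) or "(none)"),
            "protective candidates:     "
            + (", ".join(self.report["protective_candidates"]) or "(none)"),
        ]
        if "ifng_index_contrast" in self.report:
            c = self.report["ifng_index_contrast"]
            lines.append(
                f"IFN-gamma index contrast: chi2={c['chi2']:.3f}, p={c['p']:.3g} "
                f"(n_high={c['n_high']}, n_low={c['n_low']})"
            )
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.report, indent=2, sort_keys=True) + "\n"
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text


def run_screen(expression_path, clinical_path, cells_dir, out_dir=None,
               candidates=None, signature=None,
               config: ScreenConfig | None = None,
               seed: int | None = None) -> ScreenResults:
    """File-based entry point: read inputs, fit the screen, optionally write
    ``verdicts.tsv`` and ``report.json`` under ``out_dir``."""
    expression = read_expression(expression_path)
    clinical = read_clinical(clinical_path)
    cells = read_cells(cells_dir)
    model = NuclearReceptorScreen(
        expression, clinical, cells, candidates=candidates,
        signature=signature, config=config, seed=seed,
    )
    results = model.fit()
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.verdicts.to_csv(out / "verdicts.tsv", sep="\t")
        results.to_json(out / "report.json")
    return results
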