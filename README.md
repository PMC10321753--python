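# nrscreen

Prioritizing tumor-intrinsic immune-evasion genes from transcriptomics.

Melanomas that respond to immune checkpoint therapy (ICT) tend to express an
IFN-γ response signature; genes whose tumor-cell expression runs *against*
that signature — and against patient survival and ICT response — are
candidate immune-evasion regulators. `nrscreen` implements that
prioritization cascade as a tested, reusable pipeline for anyone screening a
candidate panel (here, nuclear receptors) over bulk expression with clinical
outcomes plus annotated single-cell data:

1. **IFN-γ index** — for each sample, the mean rank percentile of the ten
   IFN-γ signature genes (*IFNG, STAT1, CCR5, CXCL9, CXCL10, CXCL11, IDO1,
   PRF1, GZMA*, and an HLA-D surrogate, default *HLA-DRA*):
   `I_s = (1/10) Σ_g rank_g(s) / n`. Samples with `I > 0.75` vs `I < 0.25`
   are compared by Kaplan–Meier / log-rank.
2. **Correlation screen** — Spearman ρ of each candidate against every
   signature gene; a candidate is called positive/negative when ≥ k (default
   5) pairs are significant in one direction and none in the other.
3. **Survival screen** — extreme-quartile (≤ Q1 vs ≥ Q3) Kaplan–Meier
   stratification; label *unfavorable* when the high-expression arm has
   significantly worse survival (restricted-mean comparison), *favorable*
   when better. A `z > 2.0` high-expressor split is available for the
   effector stage.
4. **Single-cell screens** — percent of malignant cells expressing the gene
   (tumor-intrinsic filter, strict `> 10%`), and a malignant-cell Wilcoxon
   rank-sum contrast between ICT responders and nonresponders.
5. **Effector triage** — knockout-vs-control DE tables from three
   compartments (bulk tumor / sorted tumor cells / cultured cells) filtered
   at BH-adjusted p < 0.05 and |fold change| ≥ 1.5, intersected with
   direction consistency, then re-screened for correlation and survival.

A candidate passing all four stages with coherent negative orientation
(anti-signature, unfavorable survival, higher in nonresponders, expressed in
tumor cells) is an **immune-evasion candidate**; the mirror image is a
**protective candidate**.

All rank statistics (average ranks, Spearman with exact-permutation or
t-approximation p, Wilcoxon rank-sum with exact small-sample enumeration,
Benjamini–Hochberg, Kaplan–Meier, Mantel–Cox log-rank) are implemented in
`nrscreen.rank_stats` with explicit tie conventions and are cross-checked in
the test suite against scipy, statsmodels, and lifelines.

Because the cascade is usually run on cohorts that cannot ship with code,
the package includes a synthetic-cohort generator with planted ground truth
(`nrscreen.synthetic`): a latent immune-activity factor drives the signature
genes, planted receptors load on it with known sign, survival is exponential
with log-hazard linear in the planted genes, and single-cell detection
fractions differ by response group. Every screen can therefore be verified
end to end against known truth.

## Worked example

```bash
nrscreen simulate --out-dir demo --seed 7 --n-samples 400
```

writes a synthetic cohort (bulk `expression.tsv` + `clinical.tsv`, a
single-cell MTX triplet under `cells/`, three DE tables, and a
`manifest.json` recording the config, seed, and planted truth). Then:

```python
import nrscreen as nr
from nrscreen.screen import run_screen

cfg = nr.BulkCohortConfig(seed=7)            # the 48-NR candidate panel
res = run_screen("demo/expression.tsv", "demo/clinical.tsv", "demo/cells",
                 candidates=cfg.nr_genes(), seed=7)
print(res.summary())
```

prints

```
Nuclear receptor immune-evasion screen
==============================================
candidates screened              48
signature correlated              4
+ survival concordant             2
+ ICT response concordant         2
+ tumor intrinsic (> 10%)        2
----------------------------------------------
immune-evasion candidates: NR2F6
protective candidates:     NR1H3
IFN-gamma index contrast: chi2=199.712, p=2.41e-45 (n_high=84, n_low=80)
```

Reading the funnel: of 48 candidates, 4 correlate with the IFN-γ signature
(the two planted receptors plus two chance calls), 2 survive the coherent
survival and response screens, and both pass the tumor-intrinsic filter.
The planted immune-evasion receptor (negative loading −0.6, hazard log-HR
log 2) is recovered as the sole immune-evasion candidate; the planted
protective receptor lands in the mirror class. The index contrast confirms
that high-signature samples survive longer, as the cascade assumes.

The same stages are exposed as `nrscreen index`, `corr-screen`,
`surv-screen`, `sc-screen`, and `triage` subcommands, and as library
functions (`compute_index`, `screen_all`, `survival_contrast`,
`percent_expressing`, `response_contrast`, `filter_de`,
`intersect_consistent`, `triage_effectors`). The full cascade is the
`NuclearReceptorScreen` model object whose `fit()` returns a
`ScreenResults` with the verdict table, the funnel, and a deterministic JSON
report.

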