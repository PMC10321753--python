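# Methods

## The screening model

The package operationalizes a common observational argument in tumor
immunology: a gene expressed by tumor cells whose expression is (i)
anti-correlated with an IFN-γ response signature, (ii) associated with worse
overall survival, (iii) higher in patients who fail immune checkpoint
therapy (ICT), and (iv) actually expressed in malignant cells, is a
candidate tumor-intrinsic immune-evasion regulator. Each clause is a
screening stage with an explicit statistic; the pipeline computes all stages
for all candidates (no early exit) so the funnel — how many candidates
survive stages 1..k — is fully observable.

### IFN-γ index

For signature gene *g* and sample *s*, let `r_g(s)` be the average rank of
*s* among the *n* cohort samples on gene *g* (ties averaged). The index is

    I_s = (1/|G|) Σ_{g∈G} r_g(s) / n,          I_s ∈ (0, 1]

with *G* the ten-gene signature. Because it depends on the data only through
per-gene orderings, the index is invariant — bit-for-bit, since tied values
map to tied values — under any strictly increasing per-gene transform; the
cohort's z-scores, log counts, or TPM give identical indices. Samples with
`I > 0.75` versus `I < 0.25` (strict inequalities; the middle band is
excluded) are compared by Kaplan–Meier / log-rank.

The signature's "HLA-D" entry is not a single gene symbol; *HLA-DRA* is the
default surrogate and the whole signature is configurable.

### Rank-statistics kernel

All stages share one kernel (`rank_stats`) with fixed conventions:

* **Ties**: average ranks everywhere (percentiles, Spearman, rank-sum).
* **Spearman p**: by default the t-approximation
  `t = ρ √((n−2)/(1−ρ²))` with n−2 df, two-sided; an exact-permutation mode
  enumerates all n! pairings and is refused above a cap (default n = 8)
  because of factorial growth. The exact mode counts pairings with
  `|ρ| ≥ |ρ_obs| − 1e−12`; the epsilon guards float comparison of
  mathematically equal rank products.
* **Wilcoxon rank-sum**: unpaired, two-sided. Exact enumeration of all
  C(N, n_a) group assignments for pooled N ≤ 12 (with the observed tie
  pattern); otherwise the normal approximation with tie-corrected variance
  and no continuity correction. The unpaired form is used for the
  responder/nonresponder contrast (12 vs 23 patients' cells) — the groups
  are independent, so a paired (signed-rank) test would not apply.
* **Kaplan–Meier / log-rank**: deaths are processed before censorings at
  tied times, so a subject censored at an event time is still at risk there.
  The log-rank statistic accumulates hypergeometric moments per event time;
  `χ² = (O−E)²/V` with a 1-df chi-square reference. Zero total variance (no
  informative event time) yields p = 1 with a `DegenerateStatisticsWarning`
  rather than an error.
* **Benjamini–Hochberg**: step-up with a running minimum from the largest
  rank, capped at 1, clamped to be ≥ the raw p (the clamp only absorbs a
  one-ulp float dip at the top rank; mathematically the adjustment never
  falls below the raw value).

SciPy supplies only distribution tail probabilities (t, normal, chi-square).
lifelines, statsmodels, and scipy.stats appear in the test suite as
independent cross-checks, never in the implementation path.

### Stage aggregation rules

* **Correlation screen**: a candidate is *positive* when ≥ k_min (default 5
  of 10) signature pairs have p < α (default 0.05) with ρ > 0 and no pair is
  significant with ρ < 0; *negative* symmetrically; otherwise *none*. No
  multiplicity correction across candidates or pairs — the screen mirrors a
  raw-p heatmap read-out, and the α, k_min knobs are reported in the output.
  A candidate that is itself a signature gene keeps its self-pair (ρ = 1),
  flagged in the row.
* **Survival screen**: low arm = values ≤ 25th percentile, high arm =
  values ≥ 75th percentile (NumPy linear-interpolation quantiles; boundary
  values included on both sides, and a collision of the two cuts under heavy
  ties is an error rather than an ambiguous assignment). The
  favorable/unfavorable direction is decided by restricted-mean survival up
  to the shorter arm's last observed time rather than by medians, which can
  be undefined under heavy censoring; medians are still reported.
* **Tumor-intrinsic filter**: percent of malignant cells with expression
  strictly above the detection threshold (default 0 on the provided scale)
  must strictly exceed τ = 10%.
* **Response contrast**: malignant cells pooled per response group
  (cell-level, matching per-cell read-outs); this ignores within-patient
  correlation, so a patient-mean variant (`level="patient"`) is provided.
* **Coherence**: the correlation direction fixes the candidate's
  orientation; survival and response calls must match it (negative ↔
  unfavorable ↔ higher in nonresponders). Positively oriented genes form a
  separate "protective" class.
* **Effector triage**: DE filtering at BH-adjusted p < 0.05 (recomputed from
  raw p per compartment when no adjusted column is supplied) and linear fold
  change ≥ 1.5, i.e. |log2FC| ≥ log2 1.5; direction-consistent intersection
  across the three compartments; suppressive effectors must be commonly
  down-regulated by knockout, anti-signature, and unfavorable on the
  z > 2.0 split. The effector–NR correlation is reported from the bulk
  cohort but not gated on.

## The synthetic cohort

The generator plants the structure the cascade assumes and nothing more.

**Bulk.** A latent immune-activity factor u ~ N(0,1) per sample. Signature
genes are `u + σε` (σ = 0.5); the planted immune-evasion NR loads −0.6, the
planted protective NR +0.6, suppressive effectors −0.5, and 46 null NRs 0.
All genes are standardized to per-gene z-scores (population SD), so the
matrix resembles cohort z-score downloads. Survival is exponential with

    log h_s = log(1/36) + log2·z_evasionNR + log2·(z_NACC1-like + z_FKBP10-like)
              − log2·z_CXCL10 − γ·u_s,   γ = log 2

Times are months (baseline mean 36, a melanoma-scale figure). The protective
immune-factor term γ makes "high signature → good survival" co-occur with
"high planted NR → poor survival", as in the motivating cohorts; γ is not
fixed by any stated condition and log 2 was chosen once as a moderate,
realistic protective effect. Censoring is independent uniform `C = c·U`
with the scale c bisected so the realized censored fraction matches the
target (default 20%) to within sample granularity. ICT response labels are
Bernoulli with P(responder) = logistic(u).

**Single cell.** Patients default to 12 responders / 23 nonresponders, 100
cells each, with cell types drawn from fixed proportions (50% malignant,
plus T/B/macrophage/NK/endothelial/CAF). Expression is zero with probability
1 − detection and lognormal otherwise; detection defaults to 30% everywhere
except the planted shifts (evasion NR: 40% in nonresponder vs 10% in
responder malignant cells; protective NR mirrored). These sizes give ≥ 500
malignant cells per response group, enough for the detection-shift contrast
to be essentially deterministic. Values are continuous log-scale expression,
not counts — the cascade only thresholds at zero — so count-level noise
(library size, dropout curves, batch) is deliberately out of scope, and
passing tests say nothing about robustness to those artifacts.

**DE tables.** One gene universe (default 400) across three compartments.
Planted common up/down genes get |log2FC| = log2 1.5 + U(0.3, 1.5) with the
configured sign everywhere and p between 1e−8 and 1e−4; planted
inconsistent genes get strong effects with compartment-dependent signs; null
genes stay strictly below the fold-change cut with uniform p. Recovery of
the planted sets by `filter_de` + `intersect_consistent` is therefore exact
by construction — the fixture verifies the set logic, not DE-model
estimation, which this package intentionally does not perform.

Everything is bit-reproducible from the config seed (one `default_rng`
stream per generator, fixed draw order).

## Verification and calibration

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes,
from scratch: exact oracle agreement for every rank primitive; null
rejection rates for the log-rank test (30 vs 30, exponential, 20% uniform
censoring, 2000 replicates) and the index survival contrast (n = 60 cohorts
from the generator with all hazard coefficients zero, 2000 replicates);
full-pipeline recovery of the planted NR over 20 seeds at generator defaults
(n = 400 bulk samples); planted-effector recovery over 20 seeds; and the
exact invariants. Problem sizes were chosen so the whole script runs in
about a minute on one CPU while keeping Monte-Carlo error small relative to
the quantities reported.

Two calibration notes. The index-contrast null uses the generator (with all
hazard terms zero) rather than iid signature genes: with ten independent
genes the rank-percentile index concentrates tightly around 0.5 and the
fixed 0.75/0.25 cuts would select near-empty strata at n = 60; correlated
signature genes spread the index over its full range, as in real cohorts.
Second, with ~13 samples per stratum the chi-square log-rank reference is
mildly anti-conservative — a 6000-replicate estimate of the null rejection
rate at α = 0.05 is ≈ 0.061 — so 2000-replicate estimates sit near, and
occasionally above, the upper edge of a [0.035, 0.065] band by sampling
noise alone. This is inherent small-sample behavior of the test (the
implementation matches lifelines to 1e−14), not a defect.

Because the ten signature genes share one latent factor, the ten pair tests
for a null candidate are strongly dependent: a chance correlation with the
factor makes most pairs significant together, so the per-candidate
false-call rate at stage 1 is close to the pair-level α (≈ 4–5%), not
α^k_min, and a 48-candidate screen typically carries 1–3 stage-1 false
calls. The later stages remove them: over 20 seeds the planted NR is the
sole immune-evasion candidate in 20 runs with zero false positives among
the 46 nulls.

## Known limitations

* Cox regression, weighted log-rank variants, and KM confidence bands are
  out of scope, as are partial correlations and tumor-purity adjustment in
  the correlation screen.
* The survival generator is exponential (constant baseline hazard); the
  screens make no such assumption, but power figures measured on synthetic
  cohorts transfer to other hazard shapes only qualitatively.
* The z > 2.0 split computes z across the supplied cohort (sample SD);
  cohorts whose published z-scores are relative to a reference subset (e.g.
  diploid samples) will stratify slightly differently.
* Identifier matching is exact and case-sensitive; no symbol aliasing.
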