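"""Synthetic cohorts with planted ground truth.

The generators emulate the statistical structure the screening cascade
assumes, at desk scale:

* **Bulk cohort** -- a latent per-sample immune-activity factor u ~ N(0,1)
  drives the 10 signature genes (loading 1) and the planted nuclear
  receptors (signed loading, default +/-0.6); null NRs are pure noise.  All
  genes are standardized to per-gene z-scores.  Survival is exponential with
  log-hazard linear in the planted-gene z-scores (default log 2 per SD for
  the immune-evasion NR and the suppressive effectors, -log 2 for the
  protective effector) minus a protective immune-factor term; censoring is
  independent uniform, calibrated to the target fraction.
* **Single-cell cohort** -- cells with type / patient / response annotations;
  a gene is detected in a cell with a (gene, cell type, response)-specific
  fraction, and detected values are lognormal.  Defaults plant the
  immune-evasion NR at 40% detection in nonresponder vs 10% in responder
  malignant cells (and the protective NR mirrored).
* **DE tables** -- three knockout-vs-control compartments over one gene
  universe, with planted direction-consistent up/down genes (|log2FC| above
  the 1.5-fold cut, tiny p), planted direction-inconsistent genes, and null
  genes strictly below the fold-change cut with uniform p.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix

from .exceptions import ValidationError
from .signature import DEFAULT_SIGNATURE_GENES

__all__ = [
    "CELL_TYPES",
    "BulkCohortConfig",
    "ScCohortConfig",
    "DEFixtureConfig",
    "SyntheticTruth",
    "generate_bulk_cohort",
    "generate_sc_cohort",
    "generate_de_tables",
    "uniform_censoring",
]

CELL_TYPES = ("malignant", "T_cell", "B_cell", "macrophage", "NK", "endothelial", "CAF")

DE_COMPARTMENTS = ("bulk_tumor", "sorted_tumor", "cultured")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted identifiers, their roles, and realized effect sizes."""

    roles: dict            # gene -> role string
    loadings: dict         # gene -> signed loading on the immune factor
    log_hazard_ratios: dict  # gene -> log-HR per SD entering the hazard
    seed: int
    realized_censoring: float = float("nan")

    def genes_with_role(self, role: str) -> list:
        return sorted(g for g, r in self.roles.items() if r == role)


@dataclass(frozen=True)
class BulkCohortConfig:
    """Bulk expression + clinical generator settings.

    ``immune_loading`` is the magnitude of the planted NRs' signed loading on
    the latent immune factor; ``hazard_log_hr`` the log hazard ratio per SD
    of the immune-evasion NR's z-score; ``immune_protection_log_hr`` (gamma)
    the protective log-HR per SD of the immune factor itself.  Times are in
    months with a baseline mean survival of 36.
    """

    n_samples: int = 400
    n_nrs: int = 48
    signature_genes: tuple = DEFAULT_SIGNATURE_GENES
    planted_negative_nr: str = "NR2F6"
    planted_positive_nr: str = "NR1H3"
    immune_loading: float = 0.6
    hazard_log_hr: float = math.log(2.0)
    immune_protection_log_hr: float = math.log(2.0)
    effector_down: tuple = ("NACC1", "FKBP10")
    effector_up: tuple = ("CXCL10",)
    effector_loading: float = 0.5
    effector_log_hr: float = math.log(2.0)
    censor_fraction: float = 0.20
    noise_sd: float = 0.5
    baseline_mean_survival: float = 36.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ValidationError("n_samples must be >= 20")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValidationError("censor_fraction must lie in [0, 1)")
        if abs(self.immune_loading) > 1.0 or abs(self.effector_loading) > 1.0:
            raise ValidationError("|loading| must be <= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.n_nrs < 2:
            raise ValidationError("need at least the two planted NRs")

    def nr_genes(self) -> list:
        nulls = [f"NR{i:02d}" for i in range(3, self.n_nrs + 1)]
        return [self.planted_negative_nr, self.planted_positive_nr] + nulls


def uniform_censoring(times: np.ndarray, target_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independent uniform censoring calibrated to a target fraction.

    Censoring times are ``scale * U`` with U ~ Uniform(0,1); the scale is
    found by bisection so the realized censored fraction matches the target
    as closely as the sample allows.  Returns (observed time, event flag).
    """
    t = np.asarray(times, dtype=float)
    if target_fraction <= 0.0:
        return t.copy(), np.ones(t.size, dtype=int)
    u = rng.uniform(1e-12, 1.0, size=t.size)
    lo, hi = 1e-9, float(t.max() / u.min()) * 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(mid * u < t))  # fraction censored
        if frac > target_fraction:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    c = scale * u
    event = (t <= c).astype(int)
    obs = np.minimum(t, c)
    return obs, event


def generate_bulk_cohort(config: BulkCohortConfig | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression genes x samples, clinical table, truth)."""
    cfg = config or BulkCohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    u = rng.standard_normal(n)

    sig = list(cfg.signature_genes)
    nrs = cfg.nr_genes()
    extra_effectors = [g for g in (*cfg.effector_down, *cfg.effector_up)
                       if g not in sig and g not in nrs]
    genes = sig + nrs + extra_effectors
    if len(set(genes)) != len(genes):
        raise ValidationError("gene identifiers collide across signature/NR/effector sets")

    loadings = {g: 1.0 for g in sig}
    loadings[cfg.planted_negative_nr] = -cfg.immune_loading
    loadings[cfg.planted_positive_nr] = cfg.immune_loading
    for g in nrs[2:]:
        loadings[g] = 0.0
    for g in cfg.effector_down:
        loadings.setdefault(g, -cfg.effector_loading)
    for g in cfg.effector_up:
        loadings.setdefault(g, cfg.effector_loading)

    raw = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        raw[i] = loadings[g] * u + cfg.noise_sd * rng.standard_normal(n)
    z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)

    samples = [f"S{i + 1:04d}" for i in range(n)]
    expr = pd.DataFrame(z, index=pd.Index(genes, name="gene"), columns=samples)

    log_hrs = {g: 0.0 for g in genes}
    log_hrs[cfg.planted_negative_nr] = cfg.hazard_log_hr
    for g in cfg.effector_down:
        log_hrs[g] = cfg.effector_log_hr
    for g in cfg.effector_up:
        log_hrs[g] = -cfg.effector_log_hr

    idx = {g: i for i, g in enumerate(genes)}
    log_hazard = math.log(1.0 / cfg.baseline_mean_survival) - cfg.immune_protection_log_hr * u
    for g, b in log_hrs.items():
        if b != 0.0:
            log_hazard = log_hazard + b * z[idx[g]]
    latent_t = rng.exponential(scale=np.exp(-log_hazard))
    obs_t, event = uniform_censoring(latent_t, cfg.censor_fraction, rng)

    p_resp = 1.0 / (1.0 + np.exp(-u))
    responder = rng.uniform(size=n) < p_resp
    clinical = pd.DataFrame(
        {
            "time": obs_t,
            "event": event,
            "response": np.where(responder, "responder", "nonresponder"),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    roles = {g: "signature" for g in sig}
    roles[cfg.planted_negative_nr] = "immune_evasion_nr"
    roles[cfg.planted_positive_nr] = "protective_nr"
    for g in nrs[2:]:
        roles[g] = "null_nr"
    for g in cfg.effector_down:
        roles[g] = "suppressive_effector"
    for g in cfg.effector_up:
        roles[g] = "immune_activating_effector"

    truth = SyntheticTruth(
        roles=roles,
        loadings=loadings,
        log_hazard_ratios=log_hrs,
        seed=cfg.seed,
        realized_censoring=float(np.mean(event == 0)),
    )
    return expr, clinical, truth


def _default_detection_overrides() -> dict:
    return {
        ("NR2F6", "malignant", "nonresponder"): 0.40,
        ("NR2F6", "malignant", "responder"): 0.10,
        ("NR1H3", "malignant", "responder"): 0.40,
        ("NR1H3", "malignant", "nonresponder"): 0.10,
    }


def _default_cell_type_proportions() -> dict:
    return {
        "malignant": 0.50,
        "T_cell": 0.20,
        "macrophage": 0.10,
        "B_cell": 0.05,
        "NK": 0.05,
        "endothelial": 0.05,
        "CAF": 0.05,
    }


@dataclass(frozen=True)
class ScCohortConfig:
    """Single-cell cohort settings.

    Patient counts default to the 12 responder / 23 nonresponder split of an
    anti-PD-1-treated melanoma cohort.  ``base_detection`` applies wherever
    no (gene, cell type, response) override is given; ``expression_scale`` is
    the mean of the underlying normal of the lognormal nonzero values.
    """

    n_patients: tuple = (("responder", 12), ("nonresponder", 23))
    cells_per_patient: int = 100
    cell_type_proportions: tuple = tuple(_default_cell_type_proportions().items())
    genes: tuple | None = None  # None -> the bulk cohort's default gene panel
    base_detection: float = 0.30
    detection_overrides: tuple = tuple(_default_detection_overrides().items())
    expression_scale: float = 1.0
    expression_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        props = dict(self.cell_type_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValidationError("cell type proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ValidationError("cell type proportions must be nonnegative")
        for key, frac in dict(self.detection_overrides).items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"detection fraction out of [0,1] for {key}")
        if not 0.0 <= self.base_detection <= 1.0:
            raise ValidationError("base_detection must lie in [0,1]")
        if self.cells_per_patient < 1 or not dict(self.n_patients):
            raise ValidationError("need at least one patient with at least one cell")

    def gene_panel(self) -> list:
        if self.genes is not None:
            return list(self.genes)
        bulk = BulkCohortConfig()
        extra = [g for g in (*bulk.effector_down, *bulk.effector_up)
                 if g not in bulk.signature_genes]
        return list(bulk.signature_genes) + bulk.nr_genes() + extra


def generate_sc_cohort(config: ScCohortConfig | None = None):
    """Generate (AnnData cells x genes, truth).

    ``obs`` carries ``cell_type``, ``patient``, ``response``; values are
    continuous log-scale expression, zero when undetected.
    """
    import anndata as ad

    cfg = config or ScCohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_panel()
    props = dict(cfg.cell_type_proportions)
    type_names = list(props)
    type_p = np.array([props[t] for t in type_names])
    overrides = dict(cfg.detection_overrides)

    cell_type, patient, response = [], [], []
    for resp, n_pat in dict(cfg.n_patients).items():
        prefix = "R" if resp == "responder" else "N"
        for j in range(int(n_pat)):
            pid = f"{prefix}{j + 1:02d}"
            kinds = rng.choice(type_names, size=cfg.cells_per_patient, p=type_p)
            cell_type.extend(kinds.tolist())
            patient.extend([pid] * cfg.cells_per_patient)
            response.extend([resp] * cfg.cells_per_patient)
    n_cells = len(cell_type)
    obs = pd.DataFrame(
        {"cell_type": cell_type, "patient": patient, "response": response},
        index=pd.Index([f"C{i + 1:06d}" for i in range(n_cells)], name="barcode"),
    )

    ct_arr = np.asarray(cell_type)
    resp_arr = np.asarray(response)
    X = np.zeros((n_cells, len(genes)))
    for j, gene in enumerate(genes):
        det = np.full(n_cells, cfg.base_detection)
        for (g, ct, rp), frac in overrides.items():
            if g == gene:
                det[(ct_arr == ct) & (resp_arr == rp)] = frac
        expressed = rng.uniform(size=n_cells) < det
        values = rng.lognormal(mean=cfg.expression_scale, sigma=cfg.expression_sd,
                               size=n_cells)
        X[:, j] = np.where(expressed, values, 0.0)

    adata = ad.AnnData(
        X=csr_matrix(X),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    roles = {}
    for (g, ct, rp), frac in overrides.items():
        roles.setdefault(g, "planted_detection_shift")
    truth = SyntheticTruth(
        roles=roles,
        loadings={},
        log_hazard_ratios={},
        seed=cfg.seed,
    )
    return adata, truth


@dataclass(frozen=True)
class DEFixtureConfig:
    """Three-compartment differential-expression fixture settings."""

    n_genes: int = 400
    planted_common_down: tuple = ("NACC1", "FKBP10")
    planted_common_up: tuple = ("CXCL10",)
    planted_inconsistent: tuple = ("INC01", "INC02")
    fc_cut: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        sets = [set(self.planted_common_down), set(self.planted_common_up),
                set(self.planted_inconsistent)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValidationError("planted gene sets must be disjoint")
        n_planted = sum(len(s) for s in sets)
        if self.n_genes < n_planted + 10:
            raise ValidationError("n_genes too small for the planted sets")
        if self.fc_cut <= 1.0:
            raise ValidationError("fc_cut must exceed 1")


def generate_de_tables(config: DEFixtureConfig | None = None
                       ) -> tuple[dict, SyntheticTruth]:
    """Generate {compartment: DE table} over a shared gene universe.

    Planted common up/down genes carry |log2FC| above log2(fc_cut) with the
    configured sign in every compartment and p << 0.05; inconsistent genes
    carry strong effects with signs that differ across compartments; null
    genes stay strictly below the fold-change cut with uniform p.
    """
    cfg = config or DEFixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lcut = math.log2(cfg.fc_cut)

    planted = list(cfg.planted_common_down) + list(cfg.planted_common_up) \
        + list(cfg.planted_inconsistent)
    n_null = cfg.n_genes - len(planted)
    nulls = [f"G{i + 1:04d}" for i in range(n_null)]
    universe = planted + nulls

    # sign patterns across the three compartments for inconsistent genes
    inc_patterns = [(+1, -1, +1), (-1, +1, -1), (+1, +1, -1), (-1, -1, +1)]

    tables = {}
    for c_idx, comp in enumerate(DE_COMPARTMENTS):
        lfc = np.empty(len(universe))
        pval = np.empty(len(universe))
        for i, g in enumerate(universe):
            if g in cfg.planted_common_down:
                lfc[i] = -(lcut + rng.uniform(0.3, 1.5))
                pval[i] = 10.0 ** rng.uniform(-8, -4)
            elif g in cfg.planted_common_up:
                lfc[i] = lcut + rng.uniform(0.3, 1.5)
                pval[i] = 10.0 ** rng.uniform(-8, -4)
            elif g in cfg.planted_inconsistent:
                k = cfg.planted_inconsistent.index(g)
                sign = inc_patterns[k % len(inc_patterns)][c_idx]
                lfc[i] = sign * (lcut + rng.uniform(0.3, 1.5))
                pval[i] = 10.0 ** rng.uniform(-8, -4)
            else:
                lfc[i] = rng.uniform(-0.95, 0.95) * lcut
                pval[i] = rng.uniform()
        tables[comp] = pd.DataFrame(
            {"gene": universe, "log2fc": lfc, "pval": pval}
        )

    roles = {g: "common_down" for g in cfg.planted_common_down}
    roles.update({g: "common_up" for g in cfg.planted_common_up})
    roles.update({g: "inconsistent" for g in cfg.planted_inconsistent})
    truth = SyntheticTruth(roles=roles, loadings={}, log_hazard_ratios={}, seed=cfg.seed)
    return tables, truth


def config_to_dict(cfg) -> dict:
    """JSON-serializable view of a generator config (for run manifests)."""
    d = asdict(cfg)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = [list(x) if isinstance(x, tuple) else x for x in v]
    return d
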