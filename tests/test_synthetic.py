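"""Generator contracts: determinism, standardization, censoring, planted structure."""

import numpy as np
import pandas as pd
import pytest

import nrscreen as nr
from nrscreen.synthetic import uniform_censoring


def test_bulk_determinism_bit_identical():
    cfg = nr.BulkCohortConfig(n_samples=60, seed=11)
    e1, c1, t1 = nr.generate_bulk_cohort(cfg)
    e2, c2, t2 = nr.generate_bulk_cohort(cfg)
    assert e1.equals(e2)
    assert c1.equals(c2)
    assert t1 == t2


def test_bulk_zscore_standardization(small_bulk):
    _, expr, _, _ = small_bulk
    assert np.abs(expr.mean(axis=1)).max() < 1e-6
    assert np.abs(expr.std(axis=1, ddof=0) - 1).max() < 1e-6


def test_bulk_censoring_hits_target(small_bulk):
    cfg, _, clinical, truth = small_bulk
    realized = float((clinical["event"] == 0).mean())
    assert abs(realized - cfg.censor_fraction) <= 0.05
    assert truth.realized_censoring == pytest.approx(realized)


def test_bulk_truth_covers_generated_genes(small_bulk):
    _, expr, _, truth = small_bulk
    assert set(truth.roles) == set(expr.index)
    assert truth.genes_with_role("immune_evasion_nr") == ["NR2F6"]
    assert len(truth.genes_with_role("null_nr")) == 46


def test_bulk_zero_effect_nr_is_null_like():
    cfg = nr.BulkCohortConfig(n_samples=300, immune_loading=0.0,
                              hazard_log_hr=0.0, seed=3)
    expr, _, truth = nr.generate_bulk_cohort(cfg)
    assert truth.loadings["NR2F6"] == 0.0
    row = nr.correlate_vs_signature(expr, "NR2F6")
    assert row.direction == "none"


def test_bulk_config_validation():
    with pytest.raises(nr.ValidationError):
        nr.BulkCohortConfig(n_samples=10).validate()
    with pytest.raises(nr.ValidationError):
        nr.BulkCohortConfig(censor_fraction=1.0).validate()
    with pytest.raises(nr.ValidationError):
        nr.BulkCohortConfig(immune_loading=1.5).validate()


def test_uniform_censoring_fraction_and_zero_target():
    rng = np.random.default_rng(5)
    t = rng.exponential(1.0, size=500)
    obs, event = uniform_censoring(t, 0.3, rng)
    assert abs(float((event == 0).mean()) - 0.3) <= 0.05
    assert np.all(obs <= t)
    obs0, event0 = uniform_censoring(t, 0.0, rng)
    assert np.all(event0 == 1)
    assert obs0 == pytest.approx(t)


def test_sc_determinism_and_annotations(small_cells):
    cfg, cells, _ = small_cells
    again, _ = nr.generate_sc_cohort(cfg)
    assert np.array_equal(cells.X.toarray(), again.X.toarray())
    assert cells.obs.equals(again.obs)
    n_pat = dict(cfg.n_patients)
    assert cells.n_obs == sum(n_pat.values()) * cfg.cells_per_patient
    assert set(cells.obs["response"]) == {"responder", "nonresponder"}


def test_sc_planted_detection_fractions():
    cfg = nr.ScCohortConfig(seed=2)  # defaults: >=500 malignant cells per group
    cells, _ = nr.generate_sc_cohort(cfg)
    mal = cells.obs["cell_type"] == "malignant"
    for resp, target in (("nonresponder", 40.0), ("responder", 10.0)):
        mask = (mal & (cells.obs["response"] == resp)).to_numpy()
        assert mask.sum() >= 500
        x = cells[:, "NR2F6"].X.toarray().ravel()[mask]
        pct = 100.0 * np.mean(x > 0)
        assert abs(pct - target) <= 5.0


def test_sc_zero_detection_and_single_type():
    cfg = nr.ScCohortConfig(
        n_patients=(("responder", 2), ("nonresponder", 2)),
        cells_per_patient=50,
        cell_type_proportions=(("malignant", 1.0),),
        genes=("GENE1",),
        base_detection=0.0,
        detection_overrides=(),
        seed=0,
    )
    cells, _ = nr.generate_sc_cohort(cfg)
    assert set(cells.obs["cell_type"]) == {"malignant"}
    assert cells.X.toarray().sum() == 0.0
    assert nr.percent_expressing(cells, "GENE1", "malignant") == 0.0


def test_sc_config_validation():
    with pytest.raises(nr.ValidationError):
        nr.ScCohortConfig(cell_type_proportions=(("malignant", 0.7),)).validate()
    with pytest.raises(nr.ValidationError):
        nr.ScCohortConfig(
            detection_overrides=((("g", "malignant", "responder"), 1.2),)
        ).validate()


def test_de_tables_planted_structure(de_fixture):
    cfg, tables, truth = de_fixture
    assert set(tables) == {"bulk_tumor", "sorted_tumor", "cultured"}
    lcut = np.log2(cfg.fc_cut)
    for comp, table in tables.items():
        t = table.set_index("gene")
        for g in cfg.planted_common_down:
            assert t.loc[g, "log2fc"] <= -lcut
            assert t.loc[g, "pval"] < 1e-3
        for g in cfg.planted_common_up:
            assert t.loc[g, "log2fc"] >= lcut
    # inconsistent genes flip sign across compartments
    for g in cfg.planted_inconsistent:
        signs = {np.sign(tables[c].set_index("gene").loc[g, "log2fc"]) for c in tables}
        assert len(signs) == 2
    # nulls never clear the fold-change bar
    null_genes = [g for g in tables["cultured"]["gene"] if g not in truth.roles]
    sub = tables["cultured"].set_index("gene").loc[null_genes, "log2fc"]
    assert np.abs(sub).max() < lcut


def test_de_determinism(de_fixture):
    cfg, tables, _ = de_fixture
    again, _ = nr.generate_de_tables(cfg)
    for comp in tables:
        assert tables[comp].equals(again[comp])


def test_de_config_rejects_overlapping_sets():
    with pytest.raises(nr.ValidationError):
        nr.DEFixtureConfig(planted_common_down=("A",), planted_common_up=("A",)).validate()
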