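import numpy as np
import pandas as pd
import pytest

import nrscreen as nr


@pytest.fixture(scope="session")
def small_bulk():
    """Planted bulk cohort at moderate size, shared across tests."""
    cfg = nr.BulkCohortConfig(n_samples=200, seed=7)
    expr, clinical, truth = nr.generate_bulk_cohort(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture(scope="session")
def small_cells():
    """Planted single-cell cohort small enough for fast tests."""
    cfg = nr.ScCohortConfig(
        n_patients=(("responder", 6), ("nonresponder", 8)),
        cells_per_patient=80,
        seed=7,
    )
    cells, truth = nr.generate_sc_cohort(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def de_fixture():
    cfg = nr.DEFixtureConfig(seed=7)
    tables, truth = nr.generate_de_tables(cfg)
    return cfg, tables, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def tiny_expr():
    """Deterministic 12-gene x 10-sample matrix with hand-controllable rows."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(12)]
    samples = [f"s{j}" for j in range(10)]
    return pd.DataFrame(rng.standard_normal((12, 10)), index=genes, columns=samples)
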