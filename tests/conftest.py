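import numpy as np
import pandas as pd
import pytest

from bistrat.config import RunConfig
from bistrat.preprocess import adjust_batch
from bistrat.simulate import default_design, simulate_dataset
from bistrat.types import ClinicalTable, ExpressionMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default planted design (1500 genes x 400 tumours),
    batch-adjusted, shared across tests."""
    design = default_design(seed=11)
    expr, clin, truth = simulate_dataset(design)
    adjusted = adjust_batch(expr, clin.df["cohort"].to_numpy())
    return design, expr, adjusted, clin, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted design for fast functional tests."""
    design = default_design(seed=5, n_genes=400, n_samples=150, n_biclusters=4)
    expr, clin, truth = simulate_dataset(design)
    adjusted = adjust_batch(expr, clin.df["cohort"].to_numpy())
    return design, expr, adjusted, clin, truth


@pytest.fixture()
def tiny_expression():
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)],
        [f"s{j}" for j in range(5)],
        rng.normal(7, 1, size=(6, 5)),
        gene_symbols=["A", "A", "B", "C", "C", "D"],
    )


def make_clinical(n, times, events, rng=None, cohorts=2):
    rng = rng or np.random.default_rng(1)
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "cohort": [f"c{i % cohorts}" for i in range(n)],
                "ln_status": rng.choice(["LN+", "LN-"], n, p=[0.1, 0.9]),
                "er_status": rng.choice(["ER+", "ER-"], n),
                "pgr_status": rng.choice(["PgR+", "PgR-"], n),
                "grade": rng.choice(["G1", "G2", "G3"], n),
                "subtype": rng.choice(["LumA", "LumB", "Basal"], n),
                "size_mm": rng.uniform(5, 50, n).round(1),
                "age_years": rng.uniform(30, 80, n).round(1),
                "dfs_time_years": np.asarray(times, float),
                "dfs_event": np.asarray(events, int),
            }
        )
    )


@pytest.fixture()
def cfg():
    return RunConfig(seed=0)
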