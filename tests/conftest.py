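import numpy as np
import pandas as pd
import pytest

from metabosel.feature_table import FeatureTable
from metabosel.simulate import SimulationDesign, simulate_study


def table_from_arrays(
    X,
    groups,
    qc_rows: int = 0,
    feature_ids=None,
    log_scale: bool = False,
) -> FeatureTable:
    """Build a FeatureTable from a matrix; the last ``qc_rows`` rows are QCs."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"F{j:03d}" for j in range(p)]
    n_study = n - qc_rows
    assert len(groups) == n_study
    sample_ids = [f"S{i:03d}" for i in range(n_study)] + [f"QC{i:02d}" for i in range(qc_rows)]
    sm = pd.DataFrame(
        {
            "group": list(groups) + ["QC"] * qc_rows,
            "is_qc": [False] * n_study + [True] * qc_rows,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    fm = pd.DataFrame(
        {"neutral_mass": np.linspace(100, 900, p), "rt": np.linspace(1, 15, p)},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return FeatureTable(
        pd.DataFrame(X, index=sm.index, columns=fm.index), fm, sm, log_scale=log_scale
    )


@pytest.fixture
def tiny_table():
    """4 study samples (2 per group) + 4 QCs, 3 features, no missingness."""
    rng = np.random.default_rng(0)
    X = rng.lognormal(10, 0.3, size=(8, 3))
    return table_from_arrays(X, ["a", "a", "b", "b"], qc_rows=4)


@pytest.fixture(scope="session")
def planted_study():
    """The reference simulated study: 50+50 samples, 500 features, 10 planted."""
    design = SimulationDesign(seed=11)
    return simulate_study(design)


@pytest.fixture(scope="session")
def filtered_imputed(planted_study):
    from metabosel.feature_table import apply_qa_pipeline, impute_half_min

    table, truth = planted_study
    filtered, _ = apply_qa_pipeline(table)
    imputed, _ = impute_half_min(filtered)
    return imputed, truth
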