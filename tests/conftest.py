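import numpy as np
import pandas as pd
import pytest

import tcellstrat as ts


@pytest.fixture
def small_cohort() -> ts.ExpressionCohort:
    """8 patients, 5 genes; CD8A/PDCD1/CD28 take the values 1..8 in patient
    order so percentile cutoffs are hand-checkable."""
    patients = [f"P{i}" for i in range(1, 9)]
    vals = np.arange(1.0, 9.0)
    expr = pd.DataFrame(
        {
            "CD8A": vals,
            "PDCD1": vals,
            "CD28": vals,
            "GENE1": np.ones(8),
            "GENE2": 3.0 * np.ones(8),
        },
        index=patients,
    ).T
    clinical = pd.DataFrame(
        {
            "os_months": [2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0, 23.0],
            "os_event": pd.array([1, 1, 0, 1, 1, 0, 1, 1], dtype="Int64"),
            "response": ["PR", "CR", "PD", "SD", "PD", "PR", "PD", "CR"],
        },
        index=patients,
    )
    return ts.ExpressionCohort(expression=expr, clinical=clinical)


@pytest.fixture
def survival_cohort() -> ts.ExpressionCohort:
    return ts.generate_survival_cohort(ts.SimulationConfig(seed=11, n_patients=200))


@pytest.fixture
def event_table() -> pd.DataFrame:
    return ts.generate_event_table(ts.CytometrySpec(seed=7))
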