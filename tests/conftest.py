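import numpy as np
import pandas as pd
import pytest

from seronet.cohort import CohortTable, log_transform
from seronet.panel import Analyte, FunctionalGroup, PanelMetadata, default_panel
from seronet.simulate import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def tiny_panel():
    return PanelMetadata(
        [
            Analyte("A", "Analyte A", FunctionalGroup.CYTOKINE),
            Analyte("B", "Analyte B", FunctionalGroup.CYTOKINE),
            Analyte("C", "Analyte C", FunctionalGroup.CHEMOKINE),
        ]
    )


def make_cohort(values, toxicity, panel, patient_ids=None, **kwargs):
    ids = patient_ids or [f"P{i+1:02d}" for i in range(len(values))]
    abundance = pd.DataFrame(values, index=ids, columns=panel.analyte_ids)
    abundance.index.name = "patient_id"
    return CohortTable(
        abundance=abundance,
        toxicity=pd.Series(toxicity, index=ids),
        panel=panel,
        **kwargs,
    )


@pytest.fixture
def tiny_cohort(tiny_panel):
    rng = np.random.default_rng(42)
    values = np.exp(rng.normal(3.0, 0.5, size=(12, 3)))
    return make_cohort(values, [0] * 6 + [1] * 6, tiny_panel)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (52/27 patients, 34 analytes)."""
    cohort, truth = generate_cohort(SyntheticCohortConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def default_logged(default_cohort):
    cohort, truth = default_cohort
    return log_transform(cohort), truth
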