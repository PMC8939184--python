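import numpy as np
import pandas as pd
import pytest

from exprtrend import ClinicalTable, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted trends, survival signal and pathways."""
    config = SimConfig(
        n_patients=240, n_genes=60, frac_up=0.15, frac_down=0.15,
        delta=0.8, sigma=0.5, frac_prognostic=0.5, n_pathways=10,
        pathway_size=15, n_enriched_pathways=3, seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def clinical_from_years(years, os_time=1.0, event=0, subtype="NA"):
    n = len(years)
    return ClinicalTable(pd.DataFrame({
        "patient_id": [f"p{i:03d}" for i in range(n)],
        "diagnosis_year": years,
        "os_time": np.broadcast_to(os_time, n).astype(float),
        "event": np.broadcast_to(event, n).astype(int),
        "subtype": np.broadcast_to(subtype, n),
    }))
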