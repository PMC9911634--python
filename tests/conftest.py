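import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ithsig import (
    AnalysisConfig,
    ExpressionMatrix,
    SampleAnnotation,
    SimulationParams,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mild_cohort():
    """Small cohort with weak gene-by-patient noise: NMF separates the immune
    module cleanly here, so recovery properties of the machinery are testable
    without the contamination regime of the full-noise design."""
    params = SimulationParams(
        n_patients=15,
        regions_per_patient=4,
        n_genes=600,
        n_clonal_immune=60,
        n_subclonal_immune=60,
        n_subclonal_background=120,
        patient_sd=0.2,
        seed=1,
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def small_cohort():
    """Default variance components at reduced size, for IHS-level checks."""
    params = SimulationParams(
        n_patients=8,
        regions_per_patient=3,
        n_genes=300,
        n_clonal_immune=30,
        n_subclonal_immune=30,
        n_subclonal_background=60,
        seed=3,
    )
    return simulate_cohort(params)


@pytest.fixture
def toy_expr():
    """4-sample toy matrix with hand-checkable z-scores."""
    data = pd.DataFrame(
        {
            "S1": [1.0, 2.0, 0.0, 5.0],
            "S2": [2.0, 2.0, 4.0, 5.0],
            "S3": [3.0, 4.0, 0.0, 5.0],
            "S4": [4.0, 4.0, 4.0, 5.0],
        },
        index=["M1", "M2", "M3", "FLAT"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def simple_annot():
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "patient_id": ["P1", "P1", "P2", "P2"],
                "region_id": ["R1", "R2", "R1", "R2"],
            }
        )
    )
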