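import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refstab.data import ExpressionMatrix, StudyDesign
from refstab.datasets import (
    flight_contrasts,
    load_flight_summaries,
    load_published_pvalues,
    load_published_verdicts,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def flight_summaries() -> pd.DataFrame:
    return load_flight_summaries()


@pytest.fixture(scope="session")
def published_pvalues() -> pd.DataFrame:
    return load_published_pvalues()


@pytest.fixture(scope="session")
def published_verdicts() -> pd.DataFrame:
    return load_published_verdicts()


@pytest.fixture(scope="session")
def contrasts():
    return flight_contrasts()


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 probes of 2 genes on 4 arrays, linear scale."""
    values = pd.DataFrame(
        {
            "a1": [100.0, 110.0, 10.0, 12.0],
            "a2": [120.0, 130.0, 11.0, 13.0],
            "a3": [90.0, 105.0, 9.0, 11.0],
            "a4": [95.0, 115.0, 10.5, 12.5],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
    )
    symbols = pd.Series(["G1", "G1", "G2", "G2"], index=values.index)
    return ExpressionMatrix(values, symbols, "linear")


@pytest.fixture
def toy_design() -> StudyDesign:
    return StudyDesign(
        "toy",
        {"a1": "H/W", "a2": "H/W", "a3": "ug", "a4": "ug"},
        conditions=("H/W", "ug"),
        contrasts=(("H/W", "ug"),),
    )
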