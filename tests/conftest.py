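import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pdmkit.rppa import NFIMatrix, RAW_LINEAR

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> NFIMatrix:
    """4 proteins x 3 samples, raw linear, two pathway panels."""
    values = pd.DataFrame(
        {
            "S1": [1.0, 2.0, 0.01, 4.0],
            "S2": [2.0, 2.0, 0.01, 1.0],
            "S3": [4.0, 2.0, 0.01, 2.0],
        },
        index=["P1", "P2", "P3", "P4"],
    )
    pathways = pd.Series(
        ["cell cycle", "cell cycle", "apoptosis", "apoptosis"],
        index=values.index,
    )
    return NFIMatrix(values, pathways, RAW_LINEAR)


def make_plate(
    treated: dict, vehicle: dict, model: str = "M1", drug: str = "carboplatin"
) -> pd.DataFrame:
    """Long plate table from {(dose, time): [rfu...]} and {time: [rfu...]}."""
    rows = []
    for (dose, time_h), rfus in treated.items():
        for i, r in enumerate(rfus, 1):
            rows.append((model, drug, dose, time_h, i, r, False))
    for time_h, rfus in vehicle.items():
        for i, r in enumerate(rfus, 1):
            rows.append((model, "DMSO", 0.0, time_h, i, r, True))
    return pd.DataFrame(
        rows,
        columns=["model", "drug", "dose_uM", "time_h", "replicate", "rfu", "is_vehicle"],
    )
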