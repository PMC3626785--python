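import numpy as np
import pandas as pd
import pytest

from rfshift.cohort import COLUMNS
from rfshift.design import DesignMatrix


def make_visit_row(patient_id="P1", month=0, edss=2.0, musiqol_index=60.0,
                   **overrides):
    row = {c: None for c in COLUMNS}
    row.update({
        "patient_id": patient_id, "month": month, "edss": edss,
        "pf": 70.0, "rp": 65.0, "vitality": 55.0, "bp": 60.0, "sf": 75.0,
        "re": 80.0, "mh": 70.0, "gh": 60.0, "pcs": 45.0, "mcs": 52.0,
        "musiqol_index": musiqol_index, "age": 40.0, "gender": "female",
        "education": "college", "marital": "cohabiting_married",
        "employment": "employed", "disease_duration": 8.0,
    })
    row.update(overrides)
    return row


def make_cohort_frame(rows):
    return pd.DataFrame(rows, columns=list(COLUMNS))


@pytest.fixture
def tiny_cohort_csv(tmp_path):
    """Three valid patient-visit rows."""
    df = make_cohort_frame([
        make_visit_row("P1", 0, edss=2.0),
        make_visit_row("P1", 6, edss=2.5),
        make_visit_row("P2", 0, edss=4.0),
    ])
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_design():
    """Separable one-variable regression: perfect split at 2.5."""
    return DesignMatrix(["x0"], np.array([[1.0], [2.0], [3.0], [4.0]]),
                        np.array([0.0, 0.0, 10.0, 10.0]))


def random_design(seed, n=120, p=4, signal=3.0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = signal * X[:, 0] + rng.normal(scale=noise, size=n)
    return DesignMatrix([f"x{i}" for i in range(p)], X, y)
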