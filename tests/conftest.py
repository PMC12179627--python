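import numpy as np
import pandas as pd
import pytest

from esmdyn.data import EsmTable
from esmdyn.simulate import DesignConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20-subject synthetic ESM dataset shared across read-only tests."""
    return generate_dataset(DesignConfig(n_subjects=20, n_days=7, seed=42), seed=42)


@pytest.fixture(scope="session")
def small_esm(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_items(small_dataset):
    return small_dataset[1]


@pytest.fixture()
def toy_table():
    """Hand-built 3-subject table with a missing Bluetooth count."""
    rows = []
    for j, sid in enumerate(["a", "b", "c"]):
        for i in range(3 if sid != "c" else 1):
            rows.append({
                "subject_id": sid, "beep_index": i, "t_days": 0.25 * i,
                "vigor": 8 + i, "fatigue": 6, "dejection": 5, "anger": 4,
                "bt_count": 5 * (i + j), "people_known": 1, "people_unknown": 0,
                "control": 0.5,
            })
    rows[1]["bt_count"] = np.nan
    return EsmTable(pd.DataFrame(rows))
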