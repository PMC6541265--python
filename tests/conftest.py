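import numpy as np
import pandas as pd
import pytest

from smallmeta.aggregate import aggregate_dataset
from smallmeta.data import load_dataset


@pytest.fixture(scope="session")
def dataset_rows():
    """Coded rows of every packaged study set, loaded once."""
    return {name: load_dataset(name)
            for name in ("sl2009_wb", "sl2009_dep", "b2013_swb",
                         "b2013_pwb", "b2013_dep")}


@pytest.fixture(scope="session")
def dataset_studies(dataset_rows):
    """Aggregated study-level tables (composite method, within_r=.50)."""
    return {name: aggregate_dataset(rows) for name, rows in dataset_rows.items()}


@pytest.fixture()
def toy_het():
    """Heterogeneous 5-study set with externally frozen reference values."""
    z = np.array([0.10, 0.45, 0.30, 0.60, 0.05])
    v = np.array([0.004, 0.01, 0.02, 0.04, 0.0025])
    return z, v


@pytest.fixture()
def toy_asym():
    """10-study set with a right-side excess among the imprecise studies."""
    z = np.array([0.02, 0.05, 0.08, 0.10, 0.12, 0.15, 0.45, 0.55, 0.65, 0.75])
    v = np.array([0.002, 0.003, 0.004, 0.005, 0.006, 0.008, 0.03, 0.04, 0.05, 0.06])
    return z, v


@pytest.fixture()
def mirrored_set():
    """Exactly symmetric funnel: mirrored pairs around 0.2 at equal variances."""
    center = 0.2
    offsets = np.array([0.05, 0.10, 0.18, 0.26, 0.33])
    z = np.concatenate([center + offsets, center - offsets])
    v = np.concatenate([np.array([0.01, 0.02, 0.03, 0.04, 0.05])] * 2)
    return z, v


def make_table(rows):
    """Helper: build an effect-table DataFrame from short tuples."""
    df = pd.DataFrame(
        rows, columns=["study_id", "measure", "intervention", "n_t", "n_c", "r"]
    )
    df["available_data"] = "post-msds"
    df["n_total"] = df["n_t"] + df["n_c"]
    return df[["study_id", "available_data", "measure", "intervention",
               "n_t", "n_c", "n_total", "r"]]
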