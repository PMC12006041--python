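import numpy as np
import pandas as pd
import pytest

from tcrtrack import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated study shared across tests."""
    config = SyntheticConfig(n_donors=2, cells_per_donor=600,
                             clones_per_subset=120, bulk_depth=8000, seed=11)
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def _nt_code(i, width=8):
    """Injective base-4 encoding of an integer as an ACGT string."""
    return "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(width))


def make_repertoire_frame(counts, prefix="TGTGCC"):
    """Helper: clonotype frame from a list of counts, distinct cdr3nt."""
    n = len(counts)
    df = pd.DataFrame({
        "cdr3nt": [prefix + _nt_code(i) for i in range(n)],
        "cdr3aa": "CASSF",
        "v_gene": "TRBV9",
        "j_gene": "TRBJ2-1",
        "count": counts,
    })
    df["frequency"] = df["count"] / df["count"].sum()
    return df.sort_values(["count", "cdr3nt"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
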