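import numpy as np
import pandas as pd
import pytest

from dualnod import CountMatrix, SimConfig, simulate_experiment


def make_samples(n_rep: int = 3, total: int = 10**9) -> pd.DataFrame:
    rows = []
    for t in ("WE2", "WWL2"):
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{t}_{r}",
                    "treatment": t,
                    "replicate": r,
                    "total_clean_reads": total,
                    "host_mapped": 0,
                    "symbiont_mapped": 0,
                }
            )
    return pd.DataFrame(rows)


def make_counts(array, partner: str = "host", samples: pd.DataFrame | None = None) -> CountMatrix:
    arr = np.asarray(array)
    if samples is None:
        samples = make_samples()
    cols = samples["sample_id"].tolist()[: arr.shape[1]]
    genes = [f"g{i}" for i in range(arr.shape[0])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=cols), partner)


@pytest.fixture
def samples6() -> pd.DataFrame:
    return make_samples()


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic experiment (documented default config, seed 11)."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale experiment used where full size adds nothing."""
    return simulate_experiment(
        SimConfig(seed=5, n_host_genes=600, n_symbiont_genes=300)
    )
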