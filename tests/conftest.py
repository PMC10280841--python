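import numpy as np
import pandas as pd
import pytest

from dimorphnet.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast two-module cohort with a female-biased disease effect."""
    config = CohortConfig(
        n_genes=60,
        n_samples_per_cell=10,
        module_sizes=(20, 15),
        disease_effect={0: {"F": 2.0, "M": 0.3}, 1: {"F": 1.0, "M": 1.0}},
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_edges(rows):
    """Edge DataFrame in the sorted shape correlation_edges produces."""
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"])
    df["p"] = 0.001
    df["q"] = 0.001
    df["abs"] = df["rho"].abs()
    df = df.sort_values(["abs", "gene_a", "gene_b"],
                        ascending=[False, True, True]).drop(columns="abs")
    return df.reset_index(drop=True)
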