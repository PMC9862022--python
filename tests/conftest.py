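import warnings

import pytest

import brcaprog as bp


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort at the default arm sizes, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr, clinical, truth = bp.simulate_cohort(
            bp.CohortConfig(n_genes=300), seed=3
        )
    return expr, clinical, truth


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 samples with exact decimal values."""
    import pandas as pd

    values = pd.DataFrame(
        {"S1": [1.5, 0.0, 12.25], "S2": [2.0, 3.5, 0.75]},
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
    )
    return bp.ExpressionMatrix(values=values)
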