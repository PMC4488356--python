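import numpy as np
import pandas as pd
import pytest

from chemores.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture
def tiny_expr() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.5, 1.0, 1.5], [5.0, 4.0, 3.0, 2.0]],
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def tiny_ann() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "response": ["CR", "CR", "NOCR", "NOCR"],
            "subtype": "basal",
            "cohort": "discovery",
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    cfg = SyntheticConfig(seed=7)
    expr, ann, truth = generate_cohort(cfg)
    return cfg, expr, ann, truth
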