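import dataclasses

import numpy as np
import pandas as pd
import pytest

from immunoscape.synthetic import GeneratorConfig, generate_cohort
from immunoscape.types import ExpressionMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def null_config():
    """No planted effects anywhere except the signature axis (which is
    needed for phenotype groups to exist at all)."""
    return dataclasses.replace(
        GeneratorConfig(),
        flagged_odds_ratio=1.0,
        confounder_tmb_coupling=0.0,
        tmb_lambda_coupling=0.0,
        pathway_effect=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_expression(values, state="log2", genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), state)
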