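import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ccacore import ExpressionMatrix, SyntheticCohortSpec, generate_cohort, log_transform

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def make_expr(values, genes=None, samples=None, scale="tpm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort shared by the heavier tests."""
    return generate_cohort(SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_cohort_log(default_cohort):
    return log_transform(default_cohort.expr)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
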