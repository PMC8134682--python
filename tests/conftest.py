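import numpy as np
import pandas as pd
import pytest

from iciscope import ExpressionMatrix
from iciscope.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by recovery-style tests."""
    return simulate_cohort(n_samples=120, noise_sd=0.2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def expr_matrix(values, scale="linear", gene_prefix="g", sample_prefix="s"):
    """Helper: wrap a 2-D array in an ExpressionMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )
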