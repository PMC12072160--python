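import numpy as np
import pandas as pd
import pytest

from secretofft import AbundanceMatrix, FiberSimParams, SecretomeSimParams, simulate_fiber_image


@pytest.fixture
def small_matrix():
    """4 proteins x 2 conditions x 2 replicates with one all-missing condition."""
    values = pd.DataFrame(
        {
            "CTR_1": [10.0, 20.0, np.nan, 5.0],
            "CTR_2": [12.0, 18.0, np.nan, 6.0],
            "FSH_1": [40.0, 21.0, 7.0, np.nan],
            "FSH_2": [44.0, 19.0, 8.0, np.nan],
        },
        index=["pA", "pB", "pC", "pD"],
    )
    up = pd.Series([3, 2, 2, 1], index=values.index)
    return AbundanceMatrix(values=values, unique_peptides=up)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        np.exp(rng.normal(10, 1, (50, 4))),
        index=[f"p{i}" for i in range(50)],
        columns=["CTR_1", "CTR_2", "FSH_1", "FSH_2"],
    )
    return AbundanceMatrix(values=values)


@pytest.fixture(scope="session")
def aligned_image():
    return simulate_fiber_image(FiberSimParams(kappa=8.0, n_fibers=200, seed=11))


@pytest.fixture(scope="session")
def isotropic_image():
    return simulate_fiber_image(FiberSimParams(kappa=0.0, n_fibers=200, seed=11))
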