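import numpy as np
import pandas as pd
import pytest

from regact.milp import RegressionProblem
from regact.simulate import GroundTruth, generate_regulatory_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted dataset: activator +1.5, bimodal inhibitor −1.0,
    σ = 0.2, 19 TFs, 40 samples."""
    return generate_regulatory_dataset(GroundTruth(seed=11))


@pytest.fixture(scope="session")
def planted_problem(planted_dataset):
    return RegressionProblem(planted_dataset.activities, planted_dataset.response)


@pytest.fixture()
def small_problem():
    """Tiny random instance: 4 regressors, 8 samples."""
    rng = np.random.default_rng(7)
    effects = pd.DataFrame(
        rng.normal(size=(4, 8)),
        index=[f"TF{i}" for i in range(4)],
        columns=[f"S{j}" for j in range(8)],
    )
    response = pd.Series(
        1.0 * effects.loc["TF1"] - 0.5 * effects.loc["TF3"] + 0.2
        + rng.normal(0, 0.1, 8),
        index=effects.columns,
    )
    return RegressionProblem(effects, response)
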