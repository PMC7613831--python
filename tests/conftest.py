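import numpy as np
import pandas as pd
import pytest

import renofao as rf


@pytest.fixture(scope="session")
def default_config():
    return rf.SyntheticStudyConfig(seed=1)


@pytest.fixture(scope="session")
def count_study(default_config):
    return rf.generate_count_study(default_config, "ZDF")


@pytest.fixture(scope="session")
def nmr_cohort(default_config):
    return rf.generate_nmr_cohort(default_config)


@pytest.fixture(scope="session")
def processed_cohort(nmr_cohort):
    spectra, _ = nmr_cohort
    return rf.process_cohort(spectra)


@pytest.fixture(scope="session")
def separable_benchmark():
    """20+20 samples, 200 variables, 5 strongly informative."""
    rng = np.random.default_rng(0)
    X = pd.DataFrame(
        rng.normal(size=(40, 200)), columns=[f"v{i:03d}" for i in range(200)]
    )
    y = np.array(["A"] * 20 + ["B"] * 20)
    for j in range(5):
        X.iloc[20:, j] += 3.0
    return X, y, [f"v{j:03d}" for j in range(5)]
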