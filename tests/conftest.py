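import numpy as np
import pytest

from mgwrlab import default_config, fit_mgwr, fit_ols, simulate_dataset


@pytest.fixture(scope="session")
def preset():
    """Default emulation preset (n=400, seed=11) with ground truth."""
    data, truth = simulate_dataset(default_config(seed=11))
    return data, truth


@pytest.fixture(scope="session")
def preset_mgwr(preset):
    data, _ = preset
    return fit_mgwr(data)


@pytest.fixture(scope="session")
def preset_ols(preset):
    data, _ = preset
    return fit_ols(data)


@pytest.fixture(scope="session")
def preset_truth_standardized(preset):
    """True coefficient surfaces on the scale of the standardized model.

    Covariates are generated standardized, so their surfaces rescale by
    1/sd(y); the intercept additionally absorbs the outcome centering.
    """
    data, truth = preset
    sdy = data.y.std(ddof=1)
    ybar = data.y.mean()
    beta = truth.beta / sdy
    beta[:, 0] = (truth.beta[:, 0] - ybar) / sdy
    return beta


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
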