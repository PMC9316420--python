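import numpy as np
import pandas as pd
import pytest

from dtsurv import IntervalGrid, SurvivalData


def make_data(times, events, n_cov: int = 1, seed: int = 0,
              covariates=None) -> SurvivalData:
    """Small survival dataset with arbitrary follow-up and random covariates."""
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = rng.standard_normal((times.shape[0], n_cov))
    cov = pd.DataFrame(np.atleast_2d(covariates),
                       columns=[f"x{j + 1}" for j in range(np.atleast_2d(covariates).shape[1])])
    return SurvivalData(time=times, event=np.asarray(events), covariates=cov)


@pytest.fixture
def unit_grid() -> IntervalGrid:
    """Five unit intervals on horizon 5."""
    return IntervalGrid(np.arange(6.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
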