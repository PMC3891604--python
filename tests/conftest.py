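import numpy as np
import pandas as pd
import pytest

from lagfit.growth import GrowthCurve


@pytest.fixture
def exp_curve():
    """Factory for exact exponential OD curves."""

    def make(rate=0.4, od0=0.05, t_max=12.0, dt=0.25, noise_sd=0.0, seed=0):
        t = np.arange(0.0, t_max + 1e-9, dt)
        od = od0 * np.exp(rate * t)
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            od = od * rng.lognormal(0.0, noise_sd, size=len(od))
        return GrowthCurve("w1", "strain", "HG", t, od)

    return make


@pytest.fixture
def lag_table():
    """Factory for small hand-checkable censored lag tables."""

    def make(lags, events, strain="s", **covariates):
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(lags))],
                "strain": strain,
                "lag_h": np.asarray(lags, dtype=float),
                "event": np.asarray(events, dtype=int),
            }
        )
        for name, values in covariates.items():
            df[name] = values
        return df

    return make
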