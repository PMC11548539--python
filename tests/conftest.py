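import numpy as np
import pandas as pd
import pytest

from twospamh import DailyPanel, SimConfig, simulate_user


def make_panel(T=30, seed=0, user_id="u1", with_nan=False):
    """Small hand-rolled panel with separated use/non-use days."""
    rng = np.random.default_rng(seed)
    days = pd.date_range("2021-01-01", periods=T, freq="D")
    use = rng.random(T) < 0.6
    uploads = np.where(use, rng.poisson(15, T), rng.poisson(1, T)).astype(float)
    unlocks = np.where(use, rng.poisson(40, T), rng.poisson(2, T)).astype(float)
    battery = np.where(use, rng.gamma(2, 4, T), rng.gamma(2, 1, T))
    steps = np.where(use, rng.poisson(5000, T), rng.poisson(100, T)).astype(float)
    if with_nan:
        steps[1] = np.nan
        uploads[2] = np.nan
    return DailyPanel(
        user_id=user_id,
        X=pd.DataFrame({"step_count": steps}, index=days),
        W=pd.DataFrame({"n_uploads": uploads}, index=days),
        Z=pd.DataFrame({"screen_unlocks": unlocks, "battery_variance": battery},
                       index=days),
    )


@pytest.fixture
def panel():
    return make_panel()


@pytest.fixture
def sim_panel():
    """A 100-day simulated panel with ground truth."""
    return simulate_user(SimConfig(la=0.5, lu=0.5, T=100, seed=7))
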