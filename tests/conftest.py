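import numpy as np
import pandas as pd
import pytest

import frailex as fx


@pytest.fixture(scope="session")
def gompertz_lt():
    return fx.make_gompertz_lifetable()


@pytest.fixture(scope="session")
def flat_lt():
    """Unstratified table with a constant 0.02/yr rate."""
    rows = [
        {"age": a, "year": y, "rate": 0.02}
        for a in range(0, 100)
        for y in range(2010, 2016)
    ]
    return fx.LifeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def sc1_cohort(gompertz_lt):
    """One moderate Sc1 cohort plus its latent record."""
    spec = fx.builtin_scenario("Sc1", n=800)
    data, latent = fx.generate_cohort(spec, gompertz_lt, seed=101)
    return spec, data, latent


@pytest.fixture(scope="session")
def sc1_fit(gompertz_lt):
    """A converged frailty fit on one n=2000 Sc1 cohort."""
    spec = fx.builtin_scenario("Sc1", n=2000)
    data, _ = fx.generate_cohort(spec, gompertz_lt, seed=77)
    model = fx.ExcessHazardModel(data, gompertz_lt, frailty="gamma", time_index=spec.gh.time_index)
    fit = model.fit()
    assert fit.converged
    return spec, data, model, fit
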