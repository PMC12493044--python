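import numpy as np
import pytest

import prolearn as pl
from prolearn.fitting import FitConfig, untransform


@pytest.fixture(scope="session")
def winning_spec():
    return pl.get_model(pl.WINNING_MODEL_ID)


@pytest.fixture(scope="session")
def standard_schedule():
    return pl.build_schedule(0, seed=7)


def make_agents(spec, n, seed, mu=None, sd=0.5, beta_mean=3.0):
    """Simulate n agents with parameters drawn around plausible means."""
    rng = np.random.default_rng(seed)
    if mu is None:
        mu = np.zeros(spec.n_params)
        for i, name in enumerate(spec.param_names):
            if name.startswith("beta"):
                mu[i] = np.log(beta_mean)
    datasets, truths = [], []
    for i in range(n):
        x = mu + sd * rng.standard_normal(spec.n_params)
        params = untransform(x, spec)
        sch = pl.build_schedule(int(rng.integers(0, 6)), seed=int(rng.integers(2**31)))
        sid = f"agent_{i:03d}"
        ds = pl.simulate_agent(
            params, spec, sch, seed=int(rng.integers(2**31)), subject_id=sid
        )
        datasets.append(ds)
        truths.append(params)
    return datasets, truths


@pytest.fixture(scope="session")
def quick_fit_config():
    return FitConfig(n_restarts=2, max_em_iter=12, tol=2e-3, seed=0)


def draw_params(spec, rng):
    """Random native-space parameter draw for property tests."""
    params = {}
    for name in spec.param_names:
        if name.startswith("beta"):
            params[name] = float(rng.uniform(0.2, 8.0))
        else:
            params[name] = float(rng.uniform(0.05, 0.95))
    return params


@pytest.fixture(scope="session")
def random_param_draw():
    return draw_params
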