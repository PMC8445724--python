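import numpy as np
import pytest

from poisliu import ModelData, PoissonRegression, load_english_league


def make_problem(seed, n=30, p=2, beta_scale=0.3):
    """Small random Poisson regression problem that fits comfortably."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.concatenate([[0.5], rng.uniform(-beta_scale, beta_scale, p)])
    mu = np.exp(np.column_stack([np.ones(n), X]) @ beta)
    y = rng.poisson(mu).astype(float)
    return X, y


@pytest.fixture(scope="session")
def football() -> ModelData:
    return load_english_league()


@pytest.fixture(scope="session")
def football_ml(football) -> PoissonRegression:
    return PoissonRegression().fit(football.X, football.y)


@pytest.fixture
def small_fit():
    """A converged fit on a fixed small problem, with its data."""
    X, y = make_problem(7, n=25, p=2)
    model = PoissonRegression().fit(X, y)
    assert model.converged_
    return model, X, y
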