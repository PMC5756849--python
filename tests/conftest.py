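import numpy as np
import pandas as pd
import pytest

from smoltsurv import (
    CovariateTable,
    ModelFit,
    ModelSpec,
    TrueParameters,
    build_design_table,
    generate_cohort,
    generate_environment,
)
from smoltsurv.glmm import aicc as aicc_fn


@pytest.fixture(scope="session")
def small_env():
    return generate_environment(n_years=6, cool_year_fraction=0.5, seed=5)


@pytest.fixture(scope="session")
def small_true():
    return TrueParameters(
        beta_0=-3.2,
        beta_d=-0.4,
        beta_d2=-0.2,
        beta={"t": 0.3, "I": 0.8},
        sigma_0=0.4,
        n_years=6,
        fish_per_year=800,
    )


@pytest.fixture(scope="session")
def small_cohort(small_true, small_env):
    tags, effects = generate_cohort(small_true, small_env, seed=7)
    return tags, effects


@pytest.fixture(scope="session")
def small_table(small_cohort, small_env):
    tags, _ = small_cohort
    return build_design_table(tags, small_env)


def make_fit(
    names,
    beta,
    ses=None,
    loglik=-100.0,
    n=1000,
    random_structure="R0",
    sigma=None,
    years=(2000, 2001),
) -> ModelFit:
    """Fabricate a ModelFit with a diagonal covariance for arithmetic tests."""
    names = tuple(names)
    beta = np.asarray(beta, dtype=float)
    ses = np.zeros_like(beta) if ses is None else np.asarray(ses, dtype=float)
    q = {"R0": 1, "R1": 2, "R2": 3}[random_structure]
    sigma = np.zeros(q) if sigma is None else np.asarray(sigma, dtype=float)
    spec = ModelSpec(frozenset(n for n in names if n != "intercept") | {"d"}, random_structure)
    k = len(beta) + q
    return ModelFit(
        spec=spec,
        beta_names=names,
        beta_hat=beta,
        sigma_hat=sigma,
        cov_beta=np.diag(ses**2),
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc_fn(loglik, k, n),
        converged=True,
        separation=False,
        conditional_modes=pd.DataFrame(
            np.zeros((len(years), q)),
            index=pd.Index(list(years), name="year"),
            columns=["b0", "b1", "b2"][:q],
        ),
    )


@pytest.fixture
def fit_factory():
    return make_fit
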