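import numpy as np
import pytest

from dcevalue import (
    AttributeSpec,
    EstimationResult,
    SimulationConfig,
    fit_clogit,
    search_fractional_design,
    simulate_choices,
    study_fixture,
)


@pytest.fixture(scope="session")
def fx():
    return study_fixture()


@pytest.fixture(scope="session")
def attrs(fx):
    return fx.attributes


@pytest.fixture(scope="session")
def design36(attrs):
    """A searched 36-set / 9-block design on the study attribute space."""
    return search_fractional_design(attrs, 36, 9, seed=11, n_restarts=3)


@pytest.fixture(scope="session")
def sim500(design36, fx):
    """500 intervention respondents simulated at the published coefficients."""
    cfg = SimulationConfig(
        design=design36,
        true_beta=fx.coefficients["intervention"].beta_array(),
        n_respondents={"intervention": 500},
        seed=21,
    )
    return simulate_choices(cfg)


@pytest.fixture(scope="session")
def fit500(sim500, attrs):
    return fit_clogit(sim500, attrs)


@pytest.fixture
def two_attrs():
    """A tiny 2x3 attribute space for exhaustively checkable cases."""
    return (
        AttributeSpec(name="alpha", levels=("a0", "a1")),
        AttributeSpec(name="beta", levels=("b0", "b1", "b2")),
    )


@pytest.fixture
def make_result():
    """Factory for hand-built estimation results in welfare tests."""

    def _make(names, beta, cov=None, n_individuals=10, n_sets=40):
        beta = np.asarray(beta, dtype=float)
        if cov is None:
            cov = np.eye(len(beta)) * 1e-4
        llnull = -n_sets * np.log(2.0)
        return EstimationResult(
            names=tuple(names),
            beta=beta,
            cov=np.asarray(cov, dtype=float),
            llf=llnull + 10.0,
            llnull=llnull,
            lr_stat=20.0,
            df=len(beta),
            n_individuals=n_individuals,
            n_observations=2 * n_sets,
        )

    return _make
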