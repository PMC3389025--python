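import numpy as np
import pytest

from cellml_uq import NumericCdf, RngStream
from cellml_uq.fixtures import (SpringMixtureConfig, build_example_model,
                                emit_fixture, normal_pdf_lambda,
                                run_mixture_mcmc)
from cellml_uq.mathml import (Apply, Constant, Lambda, Piecewise, VariableRef)
from cellml_uq.model import DensitySpec


def _c(v):
    return Constant(float(v), "dimensionless")


def uniform_pdf_lambda(lo=0.0, hi=1.0):
    """Uniform(lo, hi) density as a piecewise lambda."""
    x = VariableRef(None, "x")
    cond = Apply("and", (Apply("geq", (x, _c(lo))),
                         Apply("leq", (x, _c(hi)))))
    return Lambda(("x",), Piecewise(((cond, _c(1.0 / (hi - lo))),), _c(0)))


def exponential_pdf_lambda(rate=1.0):
    """Exponential(rate) density as a piecewise lambda."""
    x = VariableRef(None, "x")
    body = Apply("times", (_c(rate), Apply(
        "exp", (Apply("minus", (Apply("times", (_c(rate), x)),)),))))
    return Lambda(("x",), Piecewise(((Apply("geq", (x, _c(0))), body),),
                                    _c(0)))


@pytest.fixture(scope="session")
def std_normal_cdf():
    return NumericCdf(DensitySpec(normal_pdf_lambda(0.0, 1.0)))


@pytest.fixture(scope="session")
def spring_chain():
    config = SpringMixtureConfig()
    chain = run_mixture_mcmc(config, RngStream(20240901))
    return config, chain


@pytest.fixture(scope="session")
def example_model():
    # fixed small realisation vector; the MCMC is exercised elsewhere
    return build_example_model(
        [6.0, 6.05, 5.95, 12.0, 12.05, 11.95], (0.0, -9.81))


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return emit_fixture(str(out), seed=42, number_of_samples=10)
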