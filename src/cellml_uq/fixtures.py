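"""Regeneration of the worked example from its printed ingredients.

The example is a projectile in two dimensions under constant acceleration
with uncertain initial position and velocity.  Initial x/y position and
x velocity carry symbolic normal densities; the y velocity carries an
empirical realisation vector produced by a two-spring normal mixture
posterior: equal selection probability, per-spring mean prior N(9, 0.5^2),
per-spring variance prior Exponential(rate 20), fitted to forty calibration
values (twenty 6s, twenty 12s) with unknown spring labels.

The posterior is sampled by Metropolis-within-Gibbs: exact Gibbs updates
for the labels and (conjugate) means, random-walk Metropolis on the log
variances — the exponential prior breaks conjugacy there.  Label switching
is left alone; summaries should use label-invariant statistics such as
min/max of the means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ValidationError
from .mathml import Apply, Constant, Lambda, VariableRef
from .model import (ComponentDef, DensitySpec, ModelDocument,
                    RealisationsSpec, UncertaintyAssertion, VariableDecl)
from .sampling import RngStream
from .sedml import (DataSetSpec, ExperimentDescription, ModelRef, ReportSpec,
                    SamplingSensitivityAnalysis, TaskRef, UniformTimeCourse)
from .simulation import TimeCourseSpec

DEFAULT_ACCELERATIONS = (0.0, -9.81)  # not printed in the source material

_LOG_VARIANCE_BOUND = 60.0  # sigma^2 confined to [e^-60, e^60]


@dataclass
class SpringMixtureConfig:
    mixture_weight: float = 0.5
    prior_mean_mu: float = 9.0
    prior_sd_mu: float = 0.5
    variance_prior_rate: float = 20.0
    low_value: float = 6.0
    high_value: float = 12.0
    count_per_value: int = 20
    burn_in: int = 1000
    retained: int = 1000
    metropolis_step: float = 0.35  # log-variance walk, ~25-40% acceptance


@dataclass
class McmcChain:
    mu: np.ndarray        # (retained, 2)
    sigma2: np.ndarray    # (retained, 2)
    assignments: np.ndarray  # (retained, n_data), values in {0, 1}
    acceptance: dict = field(default_factory=dict)

    def __len__(self):
        return self.mu.shape[0]


def generate_spring_data(config: SpringMixtureConfig | None = None
                         ) -> np.ndarray:
    """The deterministic calibration dataset: twenty 6s then twenty 12s."""
    c = config or SpringMixtureConfig()
    return np.concatenate([np.full(c.count_per_value, c.low_value),
                           np.full(c.count_per_value, c.high_value)])


def _log_normal_pdf(y, mu, sigma2):
    return -0.5 * (math.log(2.0 * math.pi) + np.log(sigma2)) \
        - (y - mu) ** 2 / (2.0 * sigma2)


def run_mixture_mcmc(config: SpringMixtureConfig, rng: RngStream,
                     data: np.ndarray | None = None,
                     n_iterations: int | None = None) -> McmcChain:
    """Metropolis-within-Gibbs chain for the two-spring mixture posterior.

    ``n_iterations`` overrides ``burn_in + retained`` total sweeps (the
    burn-in fraction is kept); a spring with no assigned points falls back
    to a prior-only update rather than failing.
    """
    c = config
    y = generate_spring_data(c) if data is None else np.asarray(data, float)
    gen = rng.generator
    n = y.size
    total = n_iterations if n_iterations is not None \
        else c.burn_in + c.retained
    burn = c.burn_in if n_iterations is None \
        else int(total * c.burn_in / max(c.burn_in + c.retained, 1))

    m0, s0_sq = c.prior_mean_mu, c.prior_sd_mu ** 2
    rate, w = c.variance_prior_rate, c.mixture_weight
    log_w = np.log([w, 1.0 - w])

    mu = np.array([m0, m0], float)
    sigma2 = np.array([1.0 / rate, 1.0 / rate], float)
    s = (gen.random_sample(n) < 0.5).astype(int)

    kept_mu, kept_s2, kept_s = [], [], []
    proposals = np.zeros(2)
    accepts = np.zeros(2)

    for sweep in range(total):
        # labels: exact Gibbs, Bernoulli posterior per observation
        ll = np.stack([log_w[k] + _log_normal_pdf(y, mu[k], sigma2[k])
                       for k in (0, 1)])
        p_two = expit(ll[1] - ll[0])
        s = (gen.random_sample(n) < p_two).astype(int)

        for k in (0, 1):
            yk = y[s == k]
            nk = yk.size
            # mean: conjugate normal given labels and variance
            prec = 1.0 / s0_sq + nk / sigma2[k]
            mean = (m0 / s0_sq + yk.sum() / sigma2[k]) / prec
            mu[k] = gen.normal(mean, math.sqrt(1.0 / prec))
            # variance: random-walk Metropolis on log sigma^2
            lam = math.log(sigma2[k])
            lam_new = lam + c.metropolis_step * gen.standard_normal()
            ss = float(((yk - mu[k]) ** 2).sum())

            def log_post(l):
                return (-0.5 * nk * l - 0.5 * ss * math.exp(-l)
                        - rate * math.exp(l) + l)
            proposals[k] += 1
            accept_draw = gen.random_sample()
            # the identical printed data values make the variance posterior
            # pile up at 0; bound the walk far below anything observable so
            # arbitrarily long chains cannot underflow sigma^2
            if abs(lam_new) <= _LOG_VARIANCE_BOUND and \
                    math.log(accept_draw + 1e-300) \
                    < log_post(lam_new) - log_post(lam):
                sigma2[k] = math.exp(lam_new)
                accepts[k] += 1

        if sweep >= burn:
            kept_mu.append(mu.copy())
            kept_s2.append(sigma2.copy())
            kept_s.append(s.copy())

    return McmcChain(np.array(kept_mu), np.array(kept_s2), np.array(kept_s),
                     {"sigma2": (accepts / np.maximum(proposals, 1)).tolist()})


def posterior_predictive_realisations(chain: McmcChain,
                                      config: SpringMixtureConfig,
                                      rng: RngStream, n: int,
                                      return_indicators: bool = False):
    """Draw new velocities: chain state, then spring, then a normal draw."""
    if n <= 0:
        raise ValidationError(f"need n >= 1 predictive draws, got {n}")
    if len(chain) == 0:
        raise ValidationError("empty MCMC chain")
    gen = rng.generator
    r = len(chain)
    idx = np.minimum((gen.random_sample(n) * r).astype(int), r - 1)
    spring = (gen.random_sample(n) >= config.mixture_weight).astype(int)
    z = gen.standard_normal(n)
    values = (chain.mu[idx, spring]
              + np.sqrt(chain.sigma2[idx, spring]) * z)
    if return_indicators:
        return values, spring
    return values


# ---------------------------------------------------------------------------
# Example model and experiment documents
# ---------------------------------------------------------------------------

def _c(value: float) -> Constant:
    return Constant(float(value), "dimensionless")


def normal_pdf_lambda(mean: float, variance: float = 1.0,
                      var_name: str = "p") -> Lambda:
    """``lambda p . (1/sqrt(2 pi v)) * exp(-(p - m)^2 / (2 v))``."""
    ref = VariableRef(None, var_name)
    coef = Apply("divide", (_c(1), Apply(
        "root", (_c(2), Apply("times", (_c(2), _c(math.pi), _c(variance)))))))
    dev = Apply("minus", (ref, _c(mean))) if mean != 0 else ref
    expo = Apply("exp", (Apply("divide", (
        Apply("minus", (Apply("power", (dev, _c(2))),)),
        _c(2 * variance))),))
    return Lambda((var_name,), Apply("times", (coef, expo)))


_COMPONENT = "projectile"


def build_example_model(realisations,
                        accelerations=DEFAULT_ACCELERATIONS) -> ModelDocument:
    """Assemble the projectile model with its four uncertainty assertions."""
    realisations = tuple(float(v) for v in realisations)
    if not realisations:
        raise ValidationError("need at least one realisation for vy_init")
    ax, ay = accelerations
    cn = _COMPONENT

    def var(name, units, initial=None):
        return VariableDecl(name, units, cn, initial)

    comp = ComponentDef(cn, {
        "time": var("time", "second"),
        "x": var("x", "metre", "x_init"),
        "y": var("y", "metre", "y_init"),
        "vx": var("vx", "metre_per_second", "vx_init"),
        "vy": var("vy", "metre_per_second", "vy_init"),
        "x_init": var("x_init", "metre"),
        "y_init": var("y_init", "metre"),
        "vx_init": var("vx_init", "metre_per_second"),
        "vy_init": var("vy_init", "metre_per_second"),
        "ax": var("ax", "metre_per_second_squared", repr(float(ax))),
        "ay": var("ay", "metre_per_second_squared", repr(float(ay))),
    })

    def ref(name):
        return VariableRef(cn, name)

    def ddt(state):
        return Apply("diff", (ref("time"), ref(state)))

    assignments = [
        (ddt("x"), ref("vx"), cn),
        (ddt("y"), ref("vy"), cn),
        (ddt("vx"), ref("ax"), cn),
        (ddt("vy"), ref("ay"), cn),
    ]
    uncertainty = [
        UncertaintyAssertion((ref("x_init"),),
                             DensitySpec(normal_pdf_lambda(0.0, 1.0)), cn),
        UncertaintyAssertion((ref("y_init"),),
                             DensitySpec(normal_pdf_lambda(0.0, 1.0)), cn),
        UncertaintyAssertion((ref("vx_init"),),
                             DensitySpec(normal_pdf_lambda(10.0, 1.0)), cn),
        UncertaintyAssertion((ref("vy_init"),),
                             RealisationsSpec(realisations), cn),
    ]
    return ModelDocument(
        name="uncertain_projectile",
        components=[comp],
        assignments=assignments,
        uncertainty=uncertainty,
        units_definitions=["metre_per_second", "metre_per_second_squared"],
    )


def build_sedml_documents(number_of_samples: int,
                          model_source: str = "projectile.cellml",
                          number_of_points: int = 100):
    """The two experiment descriptions: a single run and a sensitivity run."""
    if number_of_samples < 1:
        raise ValidationError("number_of_samples must be >= 1")

    def report(task_id):
        return ReportSpec("report", [
            DataSetSpec(v, task_id, v, _COMPONENT)
            for v in ("x", "y", "vx", "vy")])

    tc = TimeCourseSpec(0.0, 0.0, 10.0, number_of_points)
    single = ExperimentDescription(
        models=[ModelRef("model1", model_source)],
        simulations=[UniformTimeCourse("sim1", tc)],
        tasks=[TaskRef("task1", "model1", "sim1")],
        outputs=[report("task1")])
    sensitivity = ExperimentDescription(
        models=[ModelRef("model1", model_source)],
        simulations=[SamplingSensitivityAnalysis(
            "sim1", tc, number_of_samples=number_of_samples)],
        tasks=[TaskRef("task1", "model1", "sim1")],
        outputs=[report("task1")])
    return single, sensitivity


def emit_fixture(out_dir, seed: int, number_of_samples: int = 100,
                 config: SpringMixtureConfig | None = None,
                 accelerations=DEFAULT_ACCELERATIONS) -> dict:
    """Full fixture pipeline: MCMC -> model file -> both SED-ML files.

    Deterministic from ``seed``.  Returns the paths written.
    """
    import os

    from .model import write_cellml
    from .sedml import write_sedml

    c = config or SpringMixtureConfig()
    rng = RngStream(seed)
    chain = run_mixture_mcmc(c, rng)
    realisations = posterior_predictive_realisations(
        chain, c, rng, c.retained)
    model = build_example_model(realisations, accelerations)
    single, sensitivity = build_sedml_documents(number_of_samples)

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "model": os.path.join(out_dir, "projectile.cellml"),
        "single_run": os.path.join(out_dir, "single_run.sedml"),
        "sensitivity": os.path.join(out_dir, "sensitivity.sedml"),
    }
    write_cellml(model, paths["model"])
    write_sedml(single, paths["single_run"])
    write_sedml(sensitivity, paths["sensitivity"])
    return paths
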