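# cellml-uq

Declarative parameter uncertainty for CellML models, with a generic
sampling engine and a SED-ML extension for Monte-Carlo sensitivity
analyses.

Uncertainty attaches to model variables through three Content MathML
`csymbol` operators under `http://www.cellml.org/uncertainty-1#`:

* `uncertainParameterWithDistribution` — asserts that a variable (or a
  vector of variables) is a random variable with a given distribution;
* `distributionFromDensity` — the distribution as a univariate p.d.f.,
  written as a one-argument MathML lambda;
* `distributionFromRealisations` — the distribution as a vector of
  realisations (scalars, or joint tuples that are always drawn whole).

Symbolic densities are sampled by inverse transform: the p.d.f. is
integrated numerically after the change of variable `w = tan(u)` (finite
limits for the improper integral), and the resulting monotone CDF is
inverted at a uniform deviate by bracketing plus damped least-squares
refinement of `(F(y) − z)²`. Realisation vectors are sampled by a uniform
index pick. A `uniformTimeCourse` SED-ML simulation carrying a
`numberOfSamples` attribute in the uncertainty namespace becomes a
sampling sensitivity analysis: that many independent parameter draws, each
integrated into a full ODE time course from one seeded Mersenne-Twister
stream.

## Layout

| module | contents |
| --- | --- |
| `cellml_uq.mathml` | Content MathML subset: parse, serialize, evaluate, compile |
| `cellml_uq.model` | CellML 1.0/1.1 I/O, uncertainty extraction, variable classification |
| `cellml_uq.sampling` | `NumericCdf`, CDF inversion, realisation picks, parameter draws |
| `cellml_uq.simulation` | evaluation plans and uniform-grid ODE time courses |
| `cellml_uq.sedml` | SED-ML subset, the `numberOfSamples` extension, CSV reports |
| `cellml_uq.fixtures` | regenerates the worked example: two-spring mixture MCMC, projectile model, both SED-ML documents |

## CLI

```sh
# emit the example model plus the two experiment descriptions
cellml-uq fixture --out example/ --seed 42 --samples 100

# structural validation / classification
cellml-uq validate --model example/projectile.cellml

# parameter draws only
cellml-uq sample --model example/projectile.cellml --n 10 --seed 1

# run an experiment and write long-format CSV reports
cellml-uq run --model example/projectile.cellml \
    --sedml example/sensitivity.sedml --seed 1 --out results/
```

Exit codes: 0 success, 1 validation failure, 2 numerical failure.
`--rel-tol`, `--abs-tol` and `--quadrature` tune the quadrature and ODE
solver; `--log-level` controls verbosity.

## Dialect notes

* The serialization of `numberOfSamples` is not pinned down by the
  operators' definition; this implementation writes it as an attribute in
  the `http://www.cellml.org/uncertainty-1#` namespace on the
  `uniformTimeCourse` element.
* Uncertainty applies are accepted in any `math` block of any component.
* Realisation elements must be constant expressions; they are evaluated
  once at load time.
* Single-document models only: `import`, RDF metadata and reactions are
  out of scope, as are discrete/multivariate densities, rejection
  sampling, and closed-form CDF inversion.
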