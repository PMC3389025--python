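"""Exception hierarchy.

Validation-type failures (bad documents, bad model structure) derive from
:class:`ValidationError`; numerical failures derive from :class:`NumericError`.
The CLI maps these onto exit codes 1 and 2 respectively.
"""


class CellmlUqError(Exception):
    """Base class for all package errors."""


class ValidationError(CellmlUqError):
    """A document or model failed structural validation."""


class MathmlParseError(ValidationError):
    """Unsupported or malformed Content MathML."""


class UnitsError(ValidationError):
    """A constant or variable is missing its required units annotation."""


class EvaluationError(CellmlUqError):
    """Expression evaluation failed (unbound symbol, domain error, ...)."""


class ModelError(ValidationError):
    """A CellML document violates the supported model structure."""


class UnderdeterminedModelError(ModelError):
    """A variable has no defining assignment, uncertainty, or initial value."""


class AlgebraicLoopError(ModelError):
    """Cyclic algebraic dependencies (DAE systems are unsupported)."""


class SedmlError(ValidationError):
    """A SED-ML document is malformed or uses unsupported features."""


class NumericError(CellmlUqError):
    """A numerical procedure failed to reach its requested tolerance."""


class DensityNormalizationError(NumericError):
    """The supplied p.d.f. does not integrate to 1 within tolerance."""

    def __init__(self, message, normalization=None):
        super().__init__(message)
        self.normalization = normalization


class IntegrationError(NumericError):
    """Quadrature or ODE integration failed; carries the best estimate."""

    def __init__(self, message, estimate=None):
        super().__init__(message)
        self.estimate = estimate


class InversionError(NumericError):
    """CDF inversion failed; carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
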