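"""Exception hierarchy for sbamix."""


class SbamixError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SbamixError, ValueError):
    """An input violates a mathematical precondition (e.g. non-positive SDI)."""


class SchemaError(SbamixError):
    """A required column is missing or a file layout is malformed."""


class ValidationError(SbamixError):
    """A plot record violates a physical invariant (e.g. components != total)."""


class EvaluationError(SbamixError):
    """A model form could not be evaluated (overflow, degenerate weights, ...)."""


class ConvergenceError(SbamixError):
    """An estimator failed to converge and cannot return a usable result."""


class SingularCovarianceError(SbamixError):
    """The cross-equation residual covariance is (near-)singular."""


class ConfigError(SbamixError):
    """A synthetic-data configuration is infeasible or inconsistent."""
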