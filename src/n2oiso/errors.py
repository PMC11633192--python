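"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: :class:`ValidationError` family -> 2,
:class:`EstimationError` -> 3, anything else -> nonzero default.
"""


class N2OIsoError(Exception):
    """Base class for all package errors."""


class ValidationError(N2OIsoError, ValueError):
    """Input violates a documented precondition or schema."""


class InsufficientDataError(ValidationError):
    """Too few independent quantities to complete a measurement."""


class InconsistencyError(ValidationError):
    """Over-determined isotopocule record disagrees beyond tolerance.

    Carries the worst absolute residual (per-mil) in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class StateError(ValidationError):
    """Operation applied to a record in the wrong state (e.g. double referencing)."""


class ConfigError(ValidationError):
    """Missing or invalid configuration (geometry, paths, rates)."""


class SchemaError(ValidationError):
    """Tabular input missing mandatory columns or containing bad cells."""


class UndefinedRatioError(ValidationError):
    """Conversion ratio requested over an interval with zero substrate consumption."""


class DegenerateInputError(ValidationError):
    """Degenerate statistical input (equal endmembers, constant regressor, ...)."""


class EstimationError(N2OIsoError, RuntimeError):
    """Monte-Carlo or fitting procedure failed to produce an estimate."""


class IntegrationError(N2OIsoError, RuntimeError):
    """Forward integration went unstable; retry with a smaller step."""
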