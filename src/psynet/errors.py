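"""Exception hierarchy shared across the package."""


class PsynetError(Exception):
    """Base class for all package errors."""


class SchemaError(PsynetError):
    """Input table does not match the declared scale schema."""


class EmptyDataError(PsynetError):
    """No rows survived validation."""


class ParameterError(PsynetError):
    """A parameter is outside its admissible range."""


class EstimationError(PsynetError):
    """Network estimation failed (degenerate input or non-convergence)."""


class ConstructionError(PsynetError):
    """A planted network could not be made positive definite."""


class StabilityError(PsynetError):
    """Too many bootstrap replicates failed."""


class ComparisonError(PsynetError):
    """Too many permutation re-estimations failed."""
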