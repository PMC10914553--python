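"""Exception hierarchy shared across the package."""


class OxyregError(Exception):
    """Base class for all package errors."""


class FormatError(OxyregError):
    """Input file does not match the expected dialect (missing columns, bad header)."""


class DataError(OxyregError):
    """Input parsed but its content violates a contract (ordering, emptiness, ranges)."""


class MetadataError(OxyregError):
    """Sample/deployment metadata is inconsistent or unknown."""


class ParameterError(OxyregError):
    """A caller-supplied parameter violates a precondition."""


class DomainError(OxyregError):
    """Numeric input outside the validated domain of a physical relation."""


class FitError(OxyregError):
    """A model fit failed (non-convergence, rank deficiency)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SingularityError(OxyregError):
    """Evaluation at a point where the expression is singular."""


class ConfigError(OxyregError):
    """Study configuration is incomplete or self-contradictory."""
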