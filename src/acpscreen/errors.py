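"""Exception hierarchy for acpscreen.

Every error raised on a contract violation derives from :class:`AcpScreenError`
so callers (and the CLI) can catch package errors without swallowing bugs.
"""


class AcpScreenError(Exception):
    """Base class for all acpscreen errors."""


class SchemaError(AcpScreenError):
    """A required column is absent or a column mapping cannot be resolved."""


class ValidationError(AcpScreenError):
    """A cell value violates a declared range or domain invariant."""


class ConsistencyError(AcpScreenError):
    """A raw score and its pre-derived binary disagree on the same record."""


class StratificationError(AcpScreenError):
    """A record is missing a value for an active stratification factor."""


class NoVariationError(AcpScreenError):
    """The outcome vector is all-0 or all-1; a slope cannot be estimated."""


class IdentifiabilityError(AcpScreenError):
    """The predictor is constant; intercept and slope are confounded."""


class NotConvergedError(AcpScreenError):
    """An operation requires a converged fit but the fit did not converge."""


class NonInvertibleError(AcpScreenError):
    """The slope is (numerically) zero; the prevalence curve has no inverse."""


class InsufficientDataError(AcpScreenError):
    """Too few populated score levels to compute the requested summary."""


class NoModelsError(AcpScreenError):
    """A registry-level operation was requested but no stratum model is fitted."""


class OrderingError(AcpScreenError):
    """A spectrum row has no computable ACP for the requested ordering key."""


class UndefinedFractionError(AcpScreenError):
    """A policy comparison against a reference that detected nobody."""


class ConfigError(AcpScreenError):
    """A run or generator configuration is internally inconsistent."""
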