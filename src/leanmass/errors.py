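"""Exception hierarchy for the pipeline.

All errors derive from :class:`LeanMassError`; most also derive from
:class:`ValueError` so they can be caught idiomatically.
"""


class LeanMassError(Exception):
    """Base class for all package errors."""


class ValidationError(LeanMassError, ValueError):
    """Input data violates a domain invariant (e.g. SG <= 1.0)."""


class ConfigurationError(LeanMassError, ValueError):
    """Invalid configuration (unknown class key, bad threshold, ...)."""


class SchemaError(LeanMassError, ValueError):
    """A file does not match its documented schema."""


class MissingMonthError(LeanMassError, KeyError):
    """A sample's collection month is absent from the FAI series."""

    def __init__(self, months):
        self.months = sorted(months)
        super().__init__(f"months missing from FAI series: {', '.join(self.months)}")


class UndefinedIndexError(LeanMassError, ValueError):
    """FAI undefined: no stems above the dbh threshold in a census."""


class SingularDesignError(LeanMassError, ValueError):
    """Design matrix is singular (e.g. all specific gravities identical)."""


class InsufficientDataError(LeanMassError, ValueError):
    """Too few observations to fit the requested model."""


class ConsistencyError(LeanMassError, ValueError):
    """Tables that must correspond row-for-row do not."""


class GenerationError(LeanMassError, ValueError):
    """Synthetic generation produced an invalid latent state."""


class ConvergenceError(LeanMassError, RuntimeError):
    """Iterative fitting failed to converge."""


class ModelSpecError(LeanMassError, ValueError):
    """Model cannot be specified on these data (e.g. a single class)."""


class PipelineStageError(LeanMassError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
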