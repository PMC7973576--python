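"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`InvisibleEcgError`, so callers
(and the CLI) can distinguish user/configuration problems from data
problems without string matching.
"""


class InvisibleEcgError(Exception):
    """Base class for all package errors."""


class FormatError(InvisibleEcgError):
    """Malformed acquisition file (header or body)."""


class ValidationError(InvisibleEcgError):
    """Data violates a structural invariant (e.g. ADC value out of range)."""


class ParameterError(InvisibleEcgError):
    """Infeasible or out-of-range configuration parameter."""


class AlignmentError(InvisibleEcgError):
    """Synchronization failed: no pulses, no matched pulses, or no overlap."""


class InsufficientDataError(InvisibleEcgError):
    """Too few beats/intervals/templates for the requested statistic."""


class UndefinedStatisticError(InvisibleEcgError):
    """The statistic is undefined for this input (constant series, zero pairs...)."""


class StageError(InvisibleEcgError):
    """Wraps an error raised inside a pipeline stage with stage context."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
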