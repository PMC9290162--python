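"""Exception hierarchy for the pipeline.

Errors are split by who can fix them: :class:`ConfigError` for malformed user
input files, :class:`ValidationError` for structurally valid input violating a
panel/spec invariant, and :class:`PipelineError` for internal consistency
failures that should never occur on valid data.
"""


class ClampError(Exception):
    """Base class for all package errors."""


class ConfigError(ClampError):
    """A configuration or input file could not be parsed; names the offending field."""


class ValidationError(ClampError):
    """Structurally valid input violates an invariant (e.g. cutoff ordering)."""


class PipelineError(ClampError):
    """Internal inconsistency during analysis (a bug, not a user error)."""


class AssignmentError(ClampError):
    """Reference-isoform assignment is impossible (e.g. zero reads); aborts the run."""
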