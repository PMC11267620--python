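"""Exception hierarchy.

``UserError`` subclasses signal bad inputs or configuration (CLI exit code 1);
anything else escaping the library is an internal error (exit code 2).
"""


class MirhdError(Exception):
    """Base class for all package errors."""


class UserError(MirhdError):
    """A problem attributable to user-supplied input or configuration."""


class ConfigurationError(UserError):
    """Invalid simulation or pipeline configuration; names the field."""


class InputError(UserError):
    """Malformed or missing input data; names the column/file."""


class NormalizationError(UserError):
    """Count normalization cannot proceed (e.g. zero-total sample)."""


class StatisticsError(UserError):
    """A statistical test's preconditions are not met (e.g. <2 replicates)."""


class AnalysisError(UserError):
    """A downstream analysis precondition failed (e.g. missing reference gene)."""


class GenerationError(UserError):
    """Synthetic-data generation cannot satisfy the requested constraints."""


class ContractError(MirhdError, ValueError):
    """An internal call-contract violation (wrong lengths, out-of-bounds)."""
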