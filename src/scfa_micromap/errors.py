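"""Exception hierarchy for the pipeline.

Data-shaped problems (malformed tables, impossible alignments, degenerate
inputs) raise :class:`DataError` subclasses; user-configuration problems
raise :class:`ConfigError`.  The CLI maps these onto exit codes 1 and 2.
"""


class ScfaMicromapError(Exception):
    """Base class for all package errors."""


class DataError(ScfaMicromapError):
    """A problem with the input data itself."""


class FormatError(DataError):
    """Malformed tabular input (negative cell, duplicate identifier, ...)."""


class AlignmentError(DataError):
    """Sample sets of paired tables cannot be aligned."""


class DomainError(DataError):
    """Values outside the mathematical domain of an operation."""


class DesignError(DataError):
    """Rank-deficient or otherwise unusable model design."""


class CoverageError(DataError):
    """Required identifiers absent from a table (e.g. module KOs)."""


class ConfigError(ScfaMicromapError):
    """Invalid user configuration."""
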