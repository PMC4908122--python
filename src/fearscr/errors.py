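"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration errors -> 2,
data-format errors -> 3, analysis errors -> 4.
"""


class FearscrError(Exception):
    """Base class for all package errors."""


class ConfigError(FearscrError):
    """Invalid configuration (paradigm, cohort spec, pipeline config)."""


class FormatError(FearscrError):
    """Malformed input file (physio, events, tables)."""


class StructuralError(FearscrError):
    """Event structure does not support the requested operation."""


class ScoringError(FearscrError):
    """Trial scoring failed (window out of bounds, empty window)."""


class AnalysisError(FearscrError):
    """Statistical computation cannot proceed on the given data."""


class DegenerateDataError(AnalysisError):
    """Data are degenerate for the requested test (e.g. zero variance)."""
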