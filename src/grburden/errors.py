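"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, FormatError and
ValidationError -> 3, AnalysisError -> 4.
"""


class GrburdenError(Exception):
    """Base class for all package errors."""


class ConfigError(GrburdenError):
    """Invalid run configuration (bad parameter values, unwritable paths)."""


class FormatError(GrburdenError):
    """Input file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(GrburdenError):
    """Input parses but violates a content invariant (duplicate ids, bad values)."""


class AnalysisError(GrburdenError):
    """A computation cannot proceed (empty variant subset, no matching variants)."""
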