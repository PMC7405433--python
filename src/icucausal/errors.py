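"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3.
"""


class ICUCausalError(Exception):
    """Base class for package errors."""


class ConfigError(ICUCausalError):
    """Invalid configuration: unknown field names, bad bounds, bad specs."""


class DataError(ICUCausalError):
    """Invalid data: impossible records, empty strata, degenerate inputs."""


class InvalidRecordError(DataError):
    """A single record violates a hard physical constraint (e.g. height <= 0)."""


class ConvergenceError(ICUCausalError):
    """An iterative fit failed to converge; carries diagnostics in args."""
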