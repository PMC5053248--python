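"""Exception hierarchy.

Every error raised deliberately by this package derives from :class:`OdastError`
so callers (and the CLI) can map failures onto categorized exit codes.
"""


class OdastError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(OdastError):
    """Invalid configuration: bad precisions, fractions, iteration counts, ..."""

    exit_code = 2


class DataError(OdastError):
    """Invalid input data: malformed rows, negative counts, bad codes."""

    exit_code = 3


class ModelAssemblyError(OdastError):
    """Latent state, masks and data do not describe the same model."""

    exit_code = 4


class DiagnosticError(OdastError):
    """A sampler or diagnostic encountered a non-finite or impossible state."""

    exit_code = 5
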