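"""Exception hierarchy shared across the package.

All errors derive from :class:`ClonofitError` so callers (and the CLI)
can trap anything the library raises with a single except clause.
"""


class ClonofitError(Exception):
    """Base class for every error raised by clonofit."""


class DataFormatError(ClonofitError, ValueError):
    """Input file or table does not have the required layout (e.g. a
    missing column)."""


class ValidationError(ClonofitError, ValueError):
    """A value violates a domain invariant (negative dose, non-positive
    surviving fraction, duplicated observation)."""


class CompletenessError(ClonofitError, ValueError):
    """A cell line is missing observations at a dose of the common grid."""


class NormalizationError(ClonofitError, ValueError):
    """Colony counts cannot be normalized (absent or empty unirradiated
    control)."""


class FitError(ClonofitError, RuntimeError):
    """A regression fit cannot be carried out (rank deficiency, too few
    observations)."""
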