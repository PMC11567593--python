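"""Exception hierarchy for the annotation pipeline.

Every error raised by this package derives from :class:`LrrwindError`, so
callers (notably the CLI) can distinguish pipeline failures from bugs.
"""


class LrrwindError(Exception):
    """Base class for all package errors."""


class ValidationError(LrrwindError, ValueError):
    """An input violates a documented precondition."""


class FormatError(LrrwindError, ValueError):
    """A structure file could not be parsed as PDB or mmCIF."""


class ChainNotFoundError(LrrwindError, KeyError):
    """The requested chain is absent, or the chain choice is ambiguous."""


class DegenerateInputError(ValidationError):
    """Input too small or too degenerate to process (e.g. < 2 CA atoms)."""


class DegenerateGeometryError(LrrwindError, ValueError):
    """Geometry breaks an assumption (zero tangent, point at the origin...).

    Carries the curve index at which the degeneracy occurred.
    """

    def __init__(self, message: str, index: int | None = None):
        self.index = index
        if index is not None:
            message = f"{message} (at index t={index})"
        super().__init__(message)


class GraphConnectivityError(LrrwindError, ValueError):
    """The mutual-kNN graph is too disconnected for circular coordinates."""
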