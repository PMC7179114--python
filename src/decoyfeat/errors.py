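"""Exception hierarchy for decoyfeat.

All exceptions derive from :class:`DecoyfeatError` so callers can catch the
package's failures with a single except clause; most also derive from the
closest builtin (``ValueError`` for bad arguments, ``RuntimeError`` for
failures that occur mid-computation).
"""


class DecoyfeatError(Exception):
    """Base class for all decoyfeat errors."""


class InvalidSpecError(DecoyfeatError, ValueError):
    """A configuration or specification object violates its invariants."""


class ShapeError(DecoyfeatError, ValueError):
    """Array dimensions do not match what an operation requires."""


class EmptySelectionError(DecoyfeatError, ValueError):
    """A structure selection (e.g. CA atoms of a chain) matched nothing."""


class PDBParseError(DecoyfeatError, ValueError):
    """A PDB record could not be parsed; the message names the line."""


class ConnectivityError(DecoyfeatError, ValueError):
    """A neighborhood graph is disconnected; suggest a larger k."""


class GapError(DecoyfeatError, ValueError):
    """A latent-walk anchor has no embedded structure within the band."""


class TrainingFailureError(DecoyfeatError, RuntimeError):
    """Optimization produced a non-finite loss; carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class ConfigurationError(DecoyfeatError, ValueError):
    """A run configuration references data that is missing or inconsistent."""
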