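"""Exception hierarchy.

All user-facing validation problems derive from :class:`ValidationError`
(itself a ``ValueError``) so callers can catch one type; fetch/network
problems are separate so the CLI can map them to a distinct exit code.
"""


class TravelTimeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TravelTimeError, ValueError):
    """Invalid input data or configuration."""


class GridError(ValidationError):
    """Grid geometry problem (degenerate extent, inconsistent spec)."""


class OutOfBoundsError(GridError):
    """A cell index or coordinate falls outside the grid."""


class FormatError(ValidationError):
    """A file does not meet the format contract (bands, georeferencing, CRS)."""


class PointsError(ValidationError):
    """Point table cannot be parsed or validated."""


class FetchError(TravelTimeError):
    """A named-surface fetch failed (network/server)."""


class OfflineError(FetchError):
    """A named surface was requested but no fetch adapter is configured."""
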