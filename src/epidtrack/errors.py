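"""Exception hierarchy for the EPID tracking-QA pipeline.

Every error raised by this package derives from :class:`EpidTrackError`,
so callers (and the CLI) can catch pipeline failures without masking
programming errors.
"""


class EpidTrackError(Exception):
    """Base class for all epidtrack errors."""


class FormatError(EpidTrackError):
    """A file does not match the declared raw dialect or image format."""


class DegenerateImageError(EpidTrackError):
    """A frame carries no contrast (all-constant counts) and cannot be normalized."""


class NoFramesError(EpidTrackError):
    """A series directory or manifest yielded zero readable frames."""


class InconsistencyError(EpidTrackError):
    """Frames within one series disagree on matrix size or dtype."""


class NoFieldError(EpidTrackError):
    """No open-field region of sufficient area was found in a frame."""


class DegenerateContourError(EpidTrackError):
    """A region is too small (single pixel) to trace a closed boundary."""


class UndefinedComError(EpidTrackError):
    """Marker center-of-mass requested for a frame with zero detected markers."""


class EmptySeriesError(EpidTrackError):
    """A tracking series contains no included frames."""


class InsufficientDataError(EpidTrackError):
    """Too few included frames (or patients) for the requested statistic."""


class ParameterError(EpidTrackError):
    """A configuration parameter is invalid for the given input."""
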