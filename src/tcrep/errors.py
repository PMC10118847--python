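"""Exception hierarchy for tcrep.

All package-specific failures derive from :class:`TcrepError` so callers
(and the CLI) can distinguish configuration, input-format and analysis
problems from programming errors.
"""


class TcrepError(Exception):
    """Base class for all tcrep errors."""


class ConfigError(TcrepError):
    """Invalid simulator or pipeline configuration."""


class FormatError(TcrepError):
    """An input table does not match any supported dialect."""


class RecordError(TcrepError):
    """One or more rows of an input table are malformed."""


class EmptySampleError(TcrepError):
    """A sample contains no rearrangements."""


class EmptyRepertoireError(TcrepError):
    """An operation requiring productive (or in-frame) records got none."""


class FrameError(TcrepError):
    """A nucleotide sequence cannot be translated (length not divisible by 3)."""


class InsufficientSupportError(TcrepError):
    """Too few histogram bins to fit a curve."""


class FitError(TcrepError):
    """Nonlinear fit failed to converge.

    Carries the deterministic initial values so a caller can report them.
    """

    def __init__(self, message: str, init: tuple | None = None):
        super().__init__(message)
        self.init = init


class QCError(TcrepError):
    """No sample passed quality control."""
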