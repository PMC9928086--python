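"""Exception hierarchy shared by all analysis modules.

CLI exit-code contract: ``ValidationError`` → 2, ``InsufficientDataError`` → 3.
"""


class LysotraceError(Exception):
    """Base class for all package errors."""


class ValidationError(LysotraceError):
    """Input violates a structural invariant (bad coordinates, bad format)."""


class InvalidParameterError(ValidationError):
    """A numeric parameter is outside its admissible range."""


class InsufficientDataError(LysotraceError):
    """Not enough observations to run the requested computation."""


class MissingDataError(LysotraceError):
    """A required input (e.g. a replicon sequence) is absent."""


class UnsupportedModeError(LysotraceError):
    """Operation undefined for this prophage integration mode."""


class NoBackgroundError(LysotraceError):
    """Background estimation impossible: every position is masked."""


class UndefinedRatioError(LysotraceError):
    """A ratio with a zero denominator was requested."""
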