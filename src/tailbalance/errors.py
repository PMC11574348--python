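"""Exception hierarchy for the tailbalance package."""


class TailBalanceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TailBalanceError):
    """A file does not conform to the expected dialect (names the offending row)."""


class IntegrityError(TailBalanceError):
    """Parsed content violates a structural invariant (bounds, frame counts)."""


class UnusableBodypartError(TailBalanceError):
    """A bodypart has no sample above the likelihood cutoff."""


class AlignmentError(TailBalanceError):
    """Two-view alignment is impossible (no centroid-visible frame)."""


class WindowError(TailBalanceError):
    """A requested analysis window does not fit inside the series."""


class ParameterError(TailBalanceError):
    """An operation parameter is out of its valid range."""


class ConfigError(TailBalanceError):
    """A configuration value is inconsistent or unknown."""


class UndefinedAngleError(TailBalanceError):
    """An angle is requested for coincident points."""


class EmptyROIError(TailBalanceError):
    """A silhouette mask has no foreground pixel (non-visible frame)."""


class ShapeError(TailBalanceError):
    """Trace lengths or shapes do not match."""
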