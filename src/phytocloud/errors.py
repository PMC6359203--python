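"""Exception hierarchy.

All package errors derive from :class:`PhytocloudError` so callers (and the CLI)
can catch one base class.
"""


class PhytocloudError(Exception):
    """Base class for all phytocloud errors."""


class ColorlessCloudError(PhytocloudError):
    """Raised when an operation needing RGB meets a cloud without colors."""


class PlyParseError(PhytocloudError):
    """Malformed PLY input; the message names the offending element/line."""


class DegenerateMeasurementError(PhytocloudError):
    """Scale-calibration input with a zero-length model-space pair."""


class FrameError(PhytocloudError):
    """Operation applied in the wrong coordinate frame (raw vs calibrated)."""


class UndefinedColorError(PhytocloudError):
    """Normalized Red is undefined because R+G+B = 0."""


class RankDeficiencyError(PhytocloudError):
    """Regression input with no spread in the predictor."""


class DegenerateNeighborhoodError(PhytocloudError):
    """Neighborhood points are coincident/collinear; no plane is defined."""


class DegenerateLeafError(PhytocloudError):
    """Leaf label missing or its points are coincident."""


class ValidationError(PhytocloudError):
    """Invalid user input (config values, label flags, file contents)."""
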