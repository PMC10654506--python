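"""Exception hierarchy shared across the package."""


class RetinotileError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RetinotileError, ValueError):
    """A numeric parameter violates its contract (e.g. non-positive spacing)."""


class InvalidInputError(RetinotileError, ValueError):
    """An input container is empty or otherwise unusable."""


class UnitError(RetinotileError, ValueError):
    """Coordinate unit or space tag does not match what the operation expects."""


class PairingError(RetinotileError, ValueError):
    """Two point patterns cannot be paired by id."""


class ConsistencyError(RetinotileError, ValueError):
    """Cross-referenced ids are missing between containers."""


class DegenerateInputError(RetinotileError, ValueError):
    """Geometry is degenerate (e.g. all points collinear)."""


class NoSignalError(RetinotileError, ValueError):
    """An activity trace carries no events to correlate against."""


class AlignmentError(RetinotileError, ValueError):
    """Trace and stimulus do not cover the same time span."""


class InsufficientDataError(RetinotileError, ValueError):
    """Too few observations remain after filtering."""


class FitFailureError(RetinotileError, RuntimeError):
    """A model fit diverged or produced out-of-range parameters."""


class FormatError(RetinotileError, ValueError):
    """A file on disk violates the expected format."""


class OutOfRangeError(RetinotileError, ValueError):
    """A requested value lies outside the range spanned by a curve."""
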