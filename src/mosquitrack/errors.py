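"""Exception hierarchy for the tracking pipeline.

Every stage raises a subclass of :class:`MosquitrackError` so the CLI can
abort with the stage name and cause without catching bare ``Exception``.
"""


class MosquitrackError(Exception):
    """Base class for all package errors."""


class ParameterError(MosquitrackError, ValueError):
    """Invalid scene, arena or algorithm parameters."""


class PlacementError(MosquitrackError):
    """Arena too small to place the requested resting anchors."""


class ParseError(MosquitrackError, ValueError):
    """Malformed input file; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MosquitrackError, ValueError):
    """Well-formed input violating a semantic constraint."""


class InsufficientDataError(MosquitrackError):
    """Operation needs more data points / frames than were supplied."""


class ExtrapolationError(MosquitrackError):
    """Spline evaluation requested outside the knot range."""


class PairingError(MosquitrackError):
    """Estimated and ground-truth tracks share no frames."""


class UndefinedMetricError(MosquitrackError):
    """A metric's denominator is empty (no defined distances)."""


class PipelineError(MosquitrackError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
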