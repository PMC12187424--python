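"""Exception hierarchy for the radar JVP pipeline.

Every stage raises a subclass of :class:`JVPRadarError` so callers can
catch pipeline failures without masking programming errors.
"""


class JVPRadarError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(JVPRadarError, ValueError):
    """A parameter value violates a documented precondition."""


class ShapeError(JVPRadarError, ValueError):
    """Raw data cannot be reshaped into the configured cube geometry."""


class ConfigurationError(JVPRadarError, ValueError):
    """A configuration value (window name, config file key) is not recognised."""


class DetectionError(JVPRadarError, RuntimeError):
    """No qualifying target/peak could be found."""


class DegenerateInputError(JVPRadarError, ValueError):
    """Input is geometrically or numerically degenerate (zero matrix,
    collinear points, too few samples)."""


class PhaseUndefinedError(JVPRadarError, ValueError):
    """A zero-magnitude I/Q sample has no phase; carries the offending index."""

    def __init__(self, index: int):
        self.index = int(index)
        super().__init__(f"phase undefined: zero-magnitude I/Q sample at frame {index}")


class InsufficientLengthError(JVPRadarError, ValueError):
    """Record is too short for the requested operation."""


class InsufficientCyclesError(JVPRadarError, ValueError):
    """Fewer cardiac cycles than template selection requires."""


class FormatError(JVPRadarError, ValueError):
    """A file on disk does not match the expected layout."""


class PipelineError(JVPRadarError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the run log
    accumulated up to the failure."""

    def __init__(self, stage: str, log, cause: Exception):
        self.stage = stage
        self.log = log
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
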