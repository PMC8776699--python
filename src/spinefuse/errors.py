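"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`SpineFuseError`
so callers (and the CLI) can distinguish validation problems, I/O problems and
registration failures by class.
"""


class SpineFuseError(Exception):
    """Base class for all spinefuse errors."""


class InvalidParameterError(SpineFuseError, ValueError):
    """A numeric argument is non-finite or out of its documented domain."""


class FormatError(SpineFuseError, ValueError):
    """A file exists but does not hold what the reader expects."""


class VolumeIOError(SpineFuseError, OSError):
    """A volume or table could not be read or written."""


class InvalidAnnotationError(SpineFuseError, ValueError):
    """The lesion annotation is empty, non-contiguous or out of range."""


class ExtractionFailureError(SpineFuseError, RuntimeError):
    """Landmark-contour extraction produced an empty mask."""


class DegenerateOverlapError(SpineFuseError, RuntimeError):
    """A candidate transform left no paired voxels to compare."""


class UndefinedCorrelationError(SpineFuseError, RuntimeError):
    """Pearson correlation requested on a constant intensity series."""


class RegistrationFailureError(SpineFuseError, RuntimeError):
    """No tested starting point produced a usable overlap."""


class InvalidRecordError(SpineFuseError, ValueError):
    """A blinded-review vote record has the wrong number of votes."""


class DegenerateTestError(SpineFuseError, RuntimeError):
    """A statistical test was handed data with zero variance."""


class StageError(SpineFuseError, RuntimeError):
    """Wraps an error from one stage of a multi-stage workflow."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
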