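"""Exception hierarchy shared across the package."""


class LeukosegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LeukosegError):
    """Raised for unsupported image formats (e.g. non-8-bit input)."""


class CapacityError(LeukosegError):
    """Raised when a container cannot represent the data (e.g. >65535 labels,
    or a synthetic scene that cannot be packed into the requested canvas)."""


class ConfigError(LeukosegError):
    """Raised for invalid or unknown configuration keys/values."""


class PipelineStageError(LeukosegError):
    """Wraps an error raised inside a pipeline stage, naming the stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
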