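"""Exception types shared across the package."""


class EchoFuseError(Exception):
    """Base class for package errors."""


class ConfigurationError(EchoFuseError, ValueError):
    """Invalid geometry, hyperparameter, or model configuration."""


class NoConeFoundError(EchoFuseError, ValueError):
    """Mask refinement removed every candidate cone pixel."""


class ManifestError(EchoFuseError, ValueError):
    """Study manifest failed validation."""


class VideoDecodeError(EchoFuseError, IOError):
    """A video file could not be decoded."""


class TrainingDivergedError(EchoFuseError, RuntimeError):
    """Loss became non-finite during training."""
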