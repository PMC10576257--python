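"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PipelineError, ValueError):
    """Invalid simulation or analysis configuration."""


class GenerationError(PipelineError, RuntimeError):
    """Synthetic data could not be generated under the requested constraints."""


class QualityError(PipelineError, RuntimeError):
    """Input image fails a basic quality check (e.g. saturated field)."""


class BoundsError(PipelineError, ValueError):
    """Geometry (path, ROI) falls outside the image bounds."""
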