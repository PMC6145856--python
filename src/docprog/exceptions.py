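"""Package-level error types."""


class ConfigurationError(ValueError):
    """A parameter or configuration value is outside its documented range."""


class GenerationError(RuntimeError):
    """Synthetic-data generation failed (e.g. invalid implied covariance)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed on otherwise valid inputs."""
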