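"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """An invalid simulation, detector, network or run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and patient."""
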