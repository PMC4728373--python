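"""Exception types shared across the pipeline stages."""


class RRBSKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RRBSKitError, ValueError):
    """Invalid parameter or configuration value."""


class NoAdapterReadsError(RRBSKitError):
    """No adapter-containing reads available to estimate conversion error."""


class PipelineStageError(RRBSKitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
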