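"""Exception hierarchy shared across the pipeline stages."""


class FatigueSigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FatigueSigError):
    """A configuration value is missing, malformed, or out of range."""


class DataError(FatigueSigError):
    """Input data violates a structural precondition (bad value, unknown id)."""


class ParseError(FatigueSigError):
    """A file could not be parsed; the message carries the line number."""


class ValidationError(FatigueSigError):
    """A domain value is outside its instrument-defined range."""


class StageError(FatigueSigError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
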