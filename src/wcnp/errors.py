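"""Exception hierarchy shared across the pipeline."""


class WcnpError(Exception):
    """Base class for all package errors."""


class ValidationError(WcnpError):
    """Input violates a documented invariant."""


class OutOfRangeError(ValidationError):
    """A value falls outside the admissible interpolation/scale range."""


class ParseError(WcnpError):
    """A file could not be parsed into the expected structure."""


class StageError(WcnpError):
    """A pipeline stage failed during computation."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
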