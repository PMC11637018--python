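class ConfigurationError(ValueError):
    """Invalid network / phantom / trainer configuration."""


class EmptyMaskError(ValueError):
    """A surface-distance metric was requested for an empty mask."""


class TrainingDivergedError(RuntimeError):
    """Loss became NaN/Inf; carries the offending global step."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"non-finite loss at step {step}")
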