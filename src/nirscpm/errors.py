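"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is internally inconsistent (e.g. band edge >= Nyquist)."""


class InputError(ValueError):
    """Input data violate a precondition (shape, finiteness, id mismatch, ...)."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
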