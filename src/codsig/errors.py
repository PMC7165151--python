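"""Exception hierarchy shared across the package."""


class CodsigError(Exception):
    """Base class for all errors raised by codsig."""


class FormatError(CodsigError):
    """A file does not conform to its declared dialect (bad header, wrong dims...)."""


class ValidationError(CodsigError):
    """Input data violate an invariant (duplicate ids, negative times, NaNs...)."""


class ConfigError(CodsigError):
    """A configuration object or file is invalid."""


class ConvergenceError(CodsigError):
    """An iterative fit failed to converge (separation, ill-conditioning...)."""


class StageError(CodsigError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")
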