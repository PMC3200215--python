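"""Exception hierarchy shared across the pipeline stages."""


class LfqError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(LfqError, ValueError):
    """A configuration object violates its invariants."""


class DataValidationError(LfqError, ValueError):
    """Input data violate a stage's preconditions."""


class FixtureParseError(DataValidationError):
    """A packaged fixture file is malformed."""

    def __init__(self, path: str, line: int, message: str):
        self.path = path
        self.line = line
        super().__init__(f"{path}, line {line}: {message}")


class AlignmentError(DataValidationError):
    """Cross-run alignment could not be established."""


class InferenceError(DataValidationError):
    """A statistical model cannot be fit on the given design."""
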