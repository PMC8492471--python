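"""Typed errors raised across the telocausal pipeline."""


class TelocausalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TelocausalError, ValueError):
    """A simulation or pipeline parameter is outside its documented range."""


class DataError(TelocausalError, ValueError):
    """An input table violates a structural invariant (missing band, bad rate...)."""


class ModelError(TelocausalError, RuntimeError):
    """A statistical model cannot be fit as requested (too few instruments,
    no incident events, undefined Wald ratio...)."""


class ParseError(TelocausalError, ValueError):
    """A file does not conform to the declared dialect; carries location info."""

    def __init__(self, message: str, *, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DependencyError(TelocausalError, RuntimeError):
    """A pipeline stage is missing the output of an upstream stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
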