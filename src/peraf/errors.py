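"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers bad inputs and configuration (CLI exit code 2);
``StageError`` covers failures inside a pipeline stage (CLI exit code 3).
"""


class PerafError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PerafError, ValueError):
    """Invalid input data, parameters, or configuration."""


class StageError(PerafError, RuntimeError):
    """A pipeline stage failed after validation passed."""

    def __init__(self, stage: str, message: str, subject: str | None = None,
                 hint: str | None = None):
        self.stage = stage
        self.subject = subject
        self.hint = hint
        parts = [f"stage '{stage}' failed"]
        if subject is not None:
            parts.append(f"subject '{subject}'")
        parts.append(message)
        if hint:
            parts.append(f"hint: {hint}")
        super().__init__(": ".join(parts))
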