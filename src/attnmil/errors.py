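"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ValueError):
    """A file on disk does not conform to the documented layout."""


class TrainingError(RuntimeError):
    """Optimization failed (e.g. the loss became non-finite)."""
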