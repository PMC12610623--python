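"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or type invariant."""


class FormatError(ValueError):
    """A file does not conform to one of the package's on-disk formats."""


class FitError(RuntimeError):
    """A curve is unusable for fitting (degenerate, too short, ...)."""
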