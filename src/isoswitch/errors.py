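"""Exception types shared across the package."""


class IsoswitchError(Exception):
    """Base class for package errors."""


class FormatError(IsoswitchError, ValueError):
    """A file does not conform to its declared dialect."""


class IntegrityError(IsoswitchError, ValueError):
    """Parsed data violate a structural invariant (duplicates, negatives, shape)."""


class ConvergenceError(IsoswitchError, RuntimeError):
    """An iterative fit failed to converge or the model is degenerate."""
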