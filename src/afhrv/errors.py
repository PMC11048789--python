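"""Exception types shared across the package."""


class AfhrvError(Exception):
    """Base class for all package errors."""


class ValidationError(AfhrvError, ValueError):
    """Input violates a documented precondition or invariant."""
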