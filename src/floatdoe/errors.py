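"""Exception hierarchy shared across the package."""


class FloatDoeError(Exception):
    """Base class for all package errors."""


class ValidationError(FloatDoeError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(FloatDoeError, ValueError):
    """A file does not conform to the expected layout (e.g. missing columns)."""


class NotFoundError(FloatDoeError, KeyError):
    """A requested product or record does not exist in the input."""
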