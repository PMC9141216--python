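"""Exception types shared across the package."""


class RilateError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RilateError, ValueError):
    """An in-memory object violates a documented invariant."""


class FormatError(RilateError, ValueError):
    """An on-disk artefact does not follow the documented layout."""


class ParseError(FormatError):
    """A cell or field could not be parsed; carries its location."""
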