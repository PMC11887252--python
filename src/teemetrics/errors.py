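"""Exception hierarchy shared across the package."""


class TeemetricsError(Exception):
    """Base class for all package-specific errors."""


class SessionFormatError(TeemetricsError):
    """A session file does not conform to the documented log dialect."""


class ValidationError(TeemetricsError):
    """An in-memory object violates one of its stated invariants."""


class DepthOutOfRangeError(TeemetricsError):
    """A requested probe depth lies outside the anatomy's navigable range.

    Callers decide whether this constitutes a simulated perforation.
    """
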