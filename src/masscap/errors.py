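"""Exception hierarchy shared across the package."""


class MasscapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MasscapError, ValueError):
    """Raised when an input record or parameter violates its invariants.

    Messages always name the offending field or row so that CSV problems
    can be traced back to the source file.
    """
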