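"""Exception types shared across the package."""


class MrsNmfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MrsNmfError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(MrsNmfError, ValueError):
    """A file on disk cannot be parsed as the expected delimited format."""
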