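"""Shared exception types."""


class CasematchError(Exception):
    """Base class for all package errors."""


class ValidationError(CasematchError, ValueError):
    """Invalid input data or configuration."""
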