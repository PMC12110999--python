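"""Exception hierarchy.

CLI exit codes: :class:`ValidationError` maps to 2, :class:`CapacityError` to 3.
"""


class ContibdError(Exception):
    """Base class for all package errors."""


class ValidationError(ContibdError):
    """Invalid input data (malformed files, inconsistent pedigrees, bad segments)."""


class ParseError(ValidationError):
    """Unparseable token or file content."""


class CapacityError(ContibdError):
    """Requested computation exceeds the configured state-space limits."""


class UndefinedLRError(ContibdError):
    """Likelihood ratio of 0/0 — both hypotheses assign zero probability."""
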