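"""Exception hierarchy for the iatdscore package.

All package-specific failures derive from :class:`IATError`, so callers can
catch one type at a pipeline boundary (the CLI does exactly that).
"""


class IATError(Exception):
    """Base class for all iatdscore errors."""


class SchemaError(IATError):
    """The input file does not expose the required columns."""


class ParseError(IATError):
    """A required column exists but holds values that cannot be parsed."""


class ValidationError(IATError):
    """Structurally parsed data violates a domain invariant."""


class UndefinedScoreError(IATError):
    """A summary statistic is requested but no defined scores exist."""
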