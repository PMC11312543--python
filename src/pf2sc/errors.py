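"""Exception hierarchy.

Errors are categorized so the command-line layer can map them to the
message classes it reports (configuration / format / validation / numeric).
"""


class Pf2Error(Exception):
    """Base class for all package errors."""

    category = "error"


class ConfigurationError(Pf2Error):
    """A required key, column or option is missing or inconsistent."""

    category = "config"


class FormatError(Pf2Error):
    """An input file does not have the expected structure."""

    category = "format"


class ValidationError(Pf2Error, ValueError):
    """Input data or arguments violate a documented precondition."""

    category = "validation"


class NumericError(Pf2Error, ArithmeticError):
    """Non-finite values or a degenerate linear-algebra subproblem."""

    category = "numeric"


class MatchingError(Pf2Error):
    """No acceptable component correspondence between two factorizations."""

    category = "validation"
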