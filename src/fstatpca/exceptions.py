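"""Exception hierarchy.

Exit-code mapping used by the CLI: 2 = parse/validation problems,
3 = geometric degeneracy (zero axis, vanishing F4-ratio denominator),
4 = a capability is missing (e.g. projecting without stored loadings).
"""


class FstatpcaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FstatpcaError):
    """Invalid input data or parameters."""

    exit_code = 2


class ParseError(ValidationError):
    """Malformed input file; message names the offending line."""


class LabelError(ValidationError):
    """A requested population label is not present."""


class DegeneracyError(FstatpcaError):
    """A geometric quantity is undefined (zero-length axis, zero denominator)."""

    exit_code = 3


class CapabilityError(FstatpcaError):
    """The object lacks the data needed for the requested operation."""

    exit_code = 4
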