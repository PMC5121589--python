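"""Exception hierarchy shared across the package."""


class AlphabandError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlphabandError):
    """A configuration field is missing or invalid; the message names the field."""


class ParameterError(AlphabandError):
    """An operation was called with out-of-contract parameters."""


class StructuralError(AlphabandError):
    """Array shapes or axes of two objects do not line up."""


class DegenerateModelError(AlphabandError):
    """A statistical model cannot be fit (constant response, collinear design)."""


class NumericalError(AlphabandError):
    """A numerical step failed (singular matrix, non-finite values)."""
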