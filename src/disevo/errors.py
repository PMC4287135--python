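"""Exception hierarchy.

``FormatError`` and ``ValidationError`` signal bad input data (CLI exit code
1); ``ParameterError`` signals a bad parameter value (exit code 2).
"""


class DisevoError(Exception):
    """Base class for all package errors."""


class FormatError(DisevoError):
    """A file could not be parsed as the expected format."""


class ValidationError(DisevoError):
    """Parsed data violates a domain invariant."""


class ParameterError(DisevoError):
    """A parameter value is outside its allowed range."""


class SimulationError(DisevoError):
    """A simulated family became degenerate (e.g. a region fully deleted)."""
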