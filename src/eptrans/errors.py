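"""Exception hierarchy.

``ValidationError`` marks bad user input (malformed tables, impossible
protocol volumes); ``ComputationError`` marks a computation that cannot be
carried out on otherwise valid input (e.g. a rate ratio with a zero
denominator requested without a fallback). The CLI maps them to exit codes
2 and 3 respectively.
"""


class EptransError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EptransError, ValueError):
    """Input fails a structural or physical precondition."""


class ComputationError(EptransError, RuntimeError):
    """Valid input, but the requested quantity cannot be computed."""
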