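"""Exception hierarchy shared across the package."""


class PaleodivError(Exception):
    """Base class for all package errors."""


class TimescaleStructureError(PaleodivError):
    """The timescale table violates a structural invariant (overlap, gap, bad ages)."""


class UnknownIntervalError(PaleodivError, KeyError):
    """An interval name is not present in the active timescale."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ResolutionError(PaleodivError):
    """A range endpoint could not be resolved at the requested rank."""


class ValidationError(PaleodivError):
    """Input data failed validation (duplicates, reversed ranges, bad flags)."""


class AlignmentError(PaleodivError):
    """Two series share no usable stages over the requested window."""


class ConfigError(PaleodivError):
    """Invalid configuration (non-positive durations, mismatched timescales...)."""
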