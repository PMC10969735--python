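"""Exception hierarchy for the m-CTSIB sway pipeline.

Every error raised on bad scientific input derives from
:class:`CtsibError`, so callers can distinguish pipeline validation
failures from programming errors.
"""


class CtsibError(Exception):
    """Base class for all pipeline errors."""


class TraceFormatError(CtsibError):
    """A trajectory file does not conform to the expected CSV layout."""


class TraceValidationError(CtsibError):
    """A parsed trace violates an invariant (time ordering, length, finiteness)."""


class ParameterError(CtsibError):
    """An operation received an out-of-range parameter."""


class MissingTrialError(CtsibError):
    """A non-familiarization trial required for averaging is absent."""


class DegenerateProfileError(CtsibError):
    """An index denominator is (numerically) zero for a participant."""


class StabilityError(CtsibError):
    """The sway simulation recursion would be unstable at the requested rate."""


class InputError(CtsibError):
    """Malformed or insufficient tabular input (manifest, block matrix, vectors)."""
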