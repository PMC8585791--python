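"""Exception hierarchy for contrafc.

All package-raised errors derive from :class:`ContrafcError` so callers can
distinguish scientific/validation failures from programming bugs.
"""


class ContrafcError(Exception):
    """Base class for all contrafc errors."""


class FormatError(ContrafcError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ContrafcError):
    """Input data violates a contract (duplicate ids, unknown labels, ...)."""


class MidlineError(ValidationError):
    """An ROI sits exactly on the midsagittal plane (x == 0 mm)."""


class ParameterError(ContrafcError):
    """A parameter value is outside its admissible range."""


class ZeroVarianceError(ContrafcError):
    """A quantity required to have positive variance is constant."""


class UndefinedCoefficientError(ContrafcError):
    """A correlation coefficient has a zero denominator."""


class QCError(ContrafcError):
    """A run or scan failed quality control."""


class PipelineError(ContrafcError):
    """A pipeline stage failed; message carries subject and stage context."""
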