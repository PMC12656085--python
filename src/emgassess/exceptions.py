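"""Exception hierarchy shared across the pipeline stages."""


class EmgAssessError(Exception):
    """Base class for all package errors."""


class FormatError(EmgAssessError, ValueError):
    """A file does not match the expected column layout or dialect."""


class ParseError(EmgAssessError, ValueError):
    """A cell could not be parsed; carries the offending row index."""


class ValidationError(EmgAssessError, ValueError):
    """A value violates its documented range or uniqueness constraint."""


class ConfigurationError(EmgAssessError, ValueError):
    """A parameter combination is outside its documented domain."""


class LengthError(EmgAssessError, ValueError):
    """A signal is too short for the requested operation."""


class DegenerateSignalError(EmgAssessError, ValueError):
    """A signal is constant/zero where variation is required."""


class DegenerateReferenceError(EmgAssessError, ValueError):
    """A normalization reference statistic is zero (e.g. dead channel)."""


class ProtocolError(EmgAssessError, RuntimeError):
    """The validation protocol could not produce a usable split."""


class LabelingError(EmgAssessError, ValueError):
    """A clinical score required for labeling is missing."""
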