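"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors (2), input/data
errors (3), statistical errors such as undefined ratios or too few
instruments (4).
"""


class CytomrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytomrError):
    """A run configuration or column mapping is invalid or incomplete."""


class InputError(CytomrError):
    """An input file or record violates the data contract."""


class UndefinedRatioError(CytomrError):
    """Wald ratio requested with a zero SNP-exposure effect."""


class InsufficientInstrumentsError(CytomrError):
    """An estimator was asked to run with fewer instruments than it supports."""
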