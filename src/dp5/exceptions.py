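"""Exception hierarchy for the dp5 package."""


class DP5Error(Exception):
    """Base class for all dp5 errors."""


class FormatError(DP5Error):
    """A structure, table or peak-list input could not be parsed."""


class DomainError(DP5Error):
    """Input is syntactically valid but chemically/numerically unusable."""


class IncompatibleParamsError(DP5Error):
    """Descriptors built with different parameter sets were mixed."""


class DegenerateKernelError(DP5Error):
    """All kernel weights underflowed to zero; a larger sigma is needed."""


class CalibrationError(DP5Error):
    """Calibration could not be fitted (e.g. too few samples per class)."""


class ConsistencyError(DP5Error):
    """Results and molecule disagree (atom counts, probability ranges...)."""


class ConfigError(DP5Error):
    """Unknown or invalid configuration key/value."""
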