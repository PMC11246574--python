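"""Exception hierarchy for mrmediate.

Errors are split by who can fix them: configuration errors (caller supplied
an invalid option), input errors (the data file or table is unusable), and
estimation errors (the statistical procedure cannot run on this dataset).
"""


class MrMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrMediateError):
    """An option, threshold, or column mapping is invalid."""


class InputError(MrMediateError):
    """An input file or table cannot be used (empty, malformed, inconsistent)."""


class InsufficientInstrumentsError(MrMediateError):
    """Too few SNPs for the requested estimator."""


class SingularDesignError(MrMediateError):
    """The exposure design matrix is rank deficient (collinear exposures)."""


class UndefinedRatioError(MrMediateError):
    """Wald ratio requested with a zero SNP-exposure effect."""


class EstimationError(MrMediateError):
    """A numerical procedure failed to converge or is undefined on this input."""
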