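"""Exception hierarchy for the MR pipeline.

Every stage raises a subclass of :class:`MrPathError` so the CLI can map any
failure to a nonzero exit with a stage-tagged message.
"""


class MrPathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrPathError):
    """Bad configuration: missing columns, unknown variants, invalid thresholds."""


class EmptyInputError(MrPathError):
    """An input table contained no usable rows."""


class NoInstrumentsError(MrPathError):
    """No variant survived genome-wide significance filtering for a trait."""


class InsufficientInstrumentsError(MrPathError):
    """Fewer instruments than the estimator's minimum (IVW 2, Egger/median 3, PRESSO 4)."""


class DegenerateFrequencyError(MrPathError):
    """Effect-allele frequency of exactly 0 or 1: variance explained undefined."""


class UndefinedRatioError(MrPathError):
    """Wald ratio with a zero exposure effect."""


class UndefinedProportionError(MrPathError):
    """Mediated proportion with a zero total effect."""


class CollinearityError(MrPathError):
    """Rank-deficient exposure matrix in multivariable MR."""


class InsufficientSampleError(MrPathError):
    """F-statistic requested with n <= k + 1."""
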