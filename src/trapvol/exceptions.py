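"""Exception and warning types shared across the package."""


class TrapvolError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TrapvolError, ValueError):
    """A parameter is outside its valid range or of the wrong kind."""


class InvalidInputError(TrapvolError, ValueError):
    """Input data (areas, gaps, tables) violates a precondition."""


class CoverageError(TrapvolError):
    """Section positions do not cover the object's support.

    Volume estimation from such a series would be biased, so it is refused.
    """


class ContractViolationError(TrapvolError):
    """A series violates the estimation-readiness contract.

    Typically the first or last section has nonzero area (the object is not
    strictly contained between the end planes), or a model-specific variance
    estimator was requested for a series with dropouts.
    """


class DegenerateInputError(TrapvolError):
    """A variance formula hit a degenerate denominator."""


class CalibrationError(TrapvolError):
    """No dispersion parameter can achieve the requested relative deviation
    under the truncation bounds of the sampling model."""


class DoublingPointNotFoundError(TrapvolError):
    """The perturbed/equidistant variance ratio never reached 2 on the
    scanned grid."""

    def __init__(self, message, counts=None, ratios=None):
        super().__init__(message)
        self.counts = counts
        self.ratios = ratios


class NegativeVarianceWarning(UserWarning):
    """A covariogram-based variance estimate came out negative and was
    clamped to zero.  This is diagnostic: it signals a pathological or very
    short section series."""
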