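"""Exception hierarchy for the pipeline."""


class MRCPLoopError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MRCPLoopError, ValueError):
    """A configuration value violates its contract."""


class InvalidArgumentError(MRCPLoopError, ValueError):
    """An operation argument violates its precondition."""


class OutOfRangeError(MRCPLoopError, ValueError):
    """A time or index falls outside the parent recording."""


class MissingChannelError(MRCPLoopError, KeyError):
    """A required channel label is absent from a recording."""


class InsufficientDataError(MRCPLoopError, ValueError):
    """Too few epochs/trials to perform the operation."""


class ConvergenceError(MRCPLoopError, RuntimeError):
    """An iterative fit failed to converge."""

    def __init__(self, message, grad_norm=None):
        super().__init__(message)
        self.grad_norm = grad_norm


class CollinearityError(MRCPLoopError, ValueError):
    """Rank-deficient design matrix; carries the offending term names."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"design matrix is rank deficient; offending terms: {self.terms}")


class UnbalancedDesignError(MRCPLoopError, ValueError):
    """A balanced subject-by-condition grid was required but not supplied."""


class ThresholdNotFoundError(MRCPLoopError, RuntimeError):
    """Resting-threshold scan exhausted the stimulator-output grid."""


class InterventionTimeoutError(MRCPLoopError, RuntimeError):
    """The stop rule was not reached within the configured event cap."""
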