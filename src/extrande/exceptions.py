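"""Exception hierarchy for the extrande package."""


class ExtrandeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ExtrandeError, ValueError):
    """A rate constant, step size or policy field violates its contract."""


class PropensityError(ExtrandeError):
    """A propensity function returned a negative or non-finite value.

    Carries the offending channel index/name so the user can locate the
    broken kinetic law.
    """

    def __init__(self, message, channel=None):
        super().__init__(message)
        self.channel = channel


class ConsistencyError(ExtrandeError):
    """A state update produced a negative copy number.

    This indicates a propensity-contract violation upstream: a reaction
    consuming a species must have zero propensity when that species is absent.
    """


class BoundViolationError(ExtrandeError):
    """The total propensity exceeded the bound B at an acceptance evaluation.

    This is a hard failure of the thinning construction (the sampled law would
    no longer be exact), never a warning.
    """


class TrajectoryRangeError(ExtrandeError, ValueError):
    """A time query fell outside the trajectory's domain [0, T]."""


class TruncationError(ExtrandeError):
    """Probability mass leaking out of the truncated state space exceeded
    tolerance; the truncation box must be enlarged."""


class ConfigError(ExtrandeError, ValueError):
    """A run configuration failed validation (unknown or missing keys)."""


class SimulationError(ExtrandeError):
    """Generic simulation failure (wraps per-cell failures in ensembles)."""
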