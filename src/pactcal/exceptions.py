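"""Exception and warning types shared across the package."""


class PactCalError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PactCalError, ValueError):
    """An input value is malformed (non-finite, wrong shape, wrong units range)."""


class InsufficientDataError(PactCalError, ValueError):
    """Too few valid measurements to pose the requested problem."""


class DegenerateGeometryError(PactCalError, ValueError):
    """The point-source arrangement does not constrain all three coordinates.

    Raised when the pairwise design matrix is rank-deficient (for example all
    sources lie in a plane) or its condition number exceeds the configured
    limit. The message names the deficient direction.
    """


class EstimationFailureError(PactCalError, RuntimeError):
    """A signal-processing step could not produce an estimate."""


class UndefinedMetricError(PactCalError, ValueError):
    """A metric is undefined for the given input (e.g. an all-zero volume)."""


class ConfigError(PactCalError, ValueError):
    """A configuration file or mapping violates the expected schema."""


class TruncationError(PactCalError, ValueError):
    """A simulated record is too short to contain a required arrival."""


class CoverageWarning(UserWarning):
    """Some voxels' arrival times fall outside the recorded time window."""


class PlausibilityWarning(UserWarning):
    """A physical quantity is outside its plausible range but not fatal."""


class ConditioningWarning(UserWarning):
    """A linear system is poorly conditioned but still solvable."""
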