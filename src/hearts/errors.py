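"""Exception hierarchy shared across the package."""


class HeartsError(Exception):
    """Base class for all package errors."""


class ParameterError(HeartsError, ValueError):
    """An argument is outside its valid domain."""


class ResolutionError(HeartsError, ValueError):
    """The grid spacing is too coarse to resolve a requested structure."""


class TopologyError(HeartsError, ValueError):
    """A geometry lacks the surfaces or connectivity an operation needs."""


class ConfigurationError(HeartsError, ValueError):
    """A stimulus or pipeline configuration is inconsistent."""


class PlacementError(HeartsError, ValueError):
    """A stimulus or electrode cannot be placed where requested."""


class ConsistencyError(HeartsError, ValueError):
    """Two inputs that must agree (e.g. fibers and geometry) do not."""


class IntegrationFailureError(HeartsError, RuntimeError):
    """Numerical integration produced non-finite state."""


class StabilityError(HeartsError, ValueError):
    """Requested time step violates the explicit-scheme stability bound."""


class NoQRSDetectedError(HeartsError, RuntimeError):
    """No QRS complex could be located in an ECG trace."""


class AmbiguityError(HeartsError, RuntimeError):
    """More than one beat found where a single beat is required."""


class AlignmentError(HeartsError, ValueError):
    """Time series that must share a time axis do not."""


class InsufficientDataError(HeartsError, ValueError):
    """A metric series has too few points for the requested statistic."""


class GapError(HeartsError, ValueError):
    """A metric series is missing an intermediate configuration."""


class ValidationError(HeartsError, ValueError):
    """A configuration file failed schema validation."""
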