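"""Exception hierarchy shared across the package."""


class GazeSteerError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(GazeSteerError):
    """Track parameters describe a degenerate or impossible geometry."""


class CoverageError(GazeSteerError):
    """A trajectory does not cover the requested arc-length window."""


class InvalidInputError(GazeSteerError):
    """An input container is empty or structurally unusable."""


class InvalidParameterError(GazeSteerError):
    """A controller or search parameter is outside its admissible range."""


class ExtrapolationError(GazeSteerError):
    """A query arc length lies outside the range spanned by the records."""


class InsufficientGazeError(GazeSteerError):
    """Fewer than two valid gaze records are available for interpolation."""


class BehindObserverError(GazeSteerError):
    """A steering point lies at or behind the observer (z_ego <= 0)."""


class DegenerateTargetError(GazeSteerError):
    """A steering point coincides with the observer position."""


class NoOverlapError(GazeSteerError):
    """Two trajectories share no arc-length interval on the reference line."""


class SimulationError(GazeSteerError):
    """A model run could not proceed (e.g., gaze coverage gap)."""


class OptimizationError(GazeSteerError):
    """Parameter search failed at every evaluated point."""


class SchemaError(GazeSteerError):
    """A data file does not match its declared schema."""


class ConfigError(GazeSteerError):
    """A run configuration is inconsistent or references unknown options."""
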