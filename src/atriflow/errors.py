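"""Exception hierarchy used across the package."""


class AtriflowError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(AtriflowError):
    """Mesh construction failed or produced an invalid mesh."""


class TaggingError(AtriflowError):
    """Required boundary/region tags are missing or inconsistent."""


class TopologyError(AtriflowError):
    """Surface is open, inconsistently oriented, or a ring is not a loop."""


class InfeasibleMotionError(AtriflowError):
    """Requested volume cannot be reached by the wall-motion model."""


class InsufficientDataError(AtriflowError):
    """Not enough samples to fit a model."""


class MeshMotionError(AtriflowError):
    """Mesh motion produced inverted or degenerate elements."""


class ScheduleError(AtriflowError):
    """A valve schedule cannot be derived from the given trace."""


class WaveDetectionError(AtriflowError):
    """E/A wave peaks could not be identified."""


class DegenerateDataError(AtriflowError):
    """Input data is degenerate for the requested fit."""


class FormatError(AtriflowError):
    """An on-disk artifact violates the expected format."""
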