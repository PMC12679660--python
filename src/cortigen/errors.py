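"""Exception hierarchy for cortigen.

Every failure mode raised by the library derives from :class:`CortigenError`
so callers (and the CLI) can catch one base class.
"""


class CortigenError(Exception):
    """Base class for all cortigen errors."""


class InvalidGeometryError(CortigenError):
    """Field geometry is unusable (non-finite positions, too few cells...)."""


class InvalidParameterError(CortigenError):
    """A numeric parameter is outside its admissible range."""


class WarmUpError(CortigenError):
    """A state update was requested with insufficient history.

    Histories must cover the maximum axonal delay plus the dendritic kernel
    support; shorter histories must be explicitly zero-padded
    (``zero_pad=True``).
    """


class UnbalancedFieldError(CortigenError):
    """Excitatory/inhibitory balance is undefined for this field.

    Raised when a neuron has no inhibitory (or no excitatory) afferents and
    the field was not flagged single-population.
    """


class DivergenceError(CortigenError):
    """A state variable became non-finite during simulation."""

    def __init__(self, step: int, variable: str):
        self.step = step
        self.variable = variable
        super().__init__(f"non-finite value in {variable!r} at step {step}")


class DegenerateVarianceError(CortigenError):
    """Eigenmode decomposition of a (near-)constant record is undefined."""


class InsufficientDataError(CortigenError):
    """Record too short for the requested lag range or window layout."""


class IncompatibleRecordsError(CortigenError):
    """Two records that must share geometry/seed do not."""


class InsufficientWindowsError(CortigenError):
    """Free-energy trajectory needs at least three windows."""


class OverCullError(CortigenError):
    """Apoptotic selection would leave fewer than two cells."""


class DegenerateLayoutError(CortigenError):
    """All soma positions coincide; spatial statistics are undefined."""


class InsufficientClustersError(CortigenError):
    """Tiling classification needs at least four cluster centers."""


class SingularCenterError(CortigenError):
    """The map center p0 is a singular point of the projection."""


class UnsupportedImageError(CortigenError):
    """Representation frames are defined for rigid moving images only."""


class ConfigError(CortigenError):
    """A run configuration failed schema validation."""


class FormatVersionError(CortigenError):
    """A record container was written by an incompatible format version."""


class CorruptRecordError(CortigenError):
    """A record container is truncated or otherwise unreadable."""
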