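"""Exception types shared across the package."""


class T1PhasorError(Exception):
    """Base class for all package-specific errors."""


class DegenerateVoxelError(T1PhasorError, ValueError):
    """A decay has non-positive total signal and no phasor can be normalized."""


class DegeneratePlaneError(T1PhasorError, ValueError):
    """The three anchor phasor vectors are (near-)collinear; no plane exists."""


class DimensionError(T1PhasorError, ValueError):
    """Phasor vector and projection plane were built from different sampling grids."""


class StateError(T1PhasorError, ValueError):
    """An operation was applied to data in the wrong state (e.g. double conversion)."""


class ConfigurationError(T1PhasorError, ValueError):
    """Invalid user-supplied configuration (overlapping intervals, bad anchors...)."""


class FormatError(T1PhasorError, ValueError):
    """An input file does not satisfy the expected on-disk contract."""
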