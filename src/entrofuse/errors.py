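"""Exception hierarchy.

Three broad families matter to callers (and to the CLI's exit codes):
configuration/usage problems, volume I/O problems, and computation
problems detected mid-pipeline.
"""


class EntrofuseError(Exception):
    """Base class for all package errors."""


class ConfigError(EntrofuseError):
    """Invalid configuration value or malformed config file."""


class InvalidSpecError(ConfigError):
    """A generator or preprocessing spec violates its own invariants."""


class VolumeIOError(EntrofuseError):
    """Base class for volume reading/writing failures."""


class MissingPathError(VolumeIOError):
    """Input path (or required parent directory) does not exist."""


class UnsupportedFormatError(VolumeIOError):
    """Requested or inferred container format is not supported."""


class UnreadableFormatError(VolumeIOError):
    """File exists but cannot be decoded as a volume."""


class MixedSliceShapesError(VolumeIOError):
    """Slices in a directory do not share a common height/width."""


class NonVolumeDatasetError(VolumeIOError):
    """HDF5 dataset (or image file) is not a 3D array."""


class ShapeMismatchError(EntrofuseError):
    """Grids that must share a shape do not."""


class NonBinaryMaskError(EntrofuseError):
    """A grid required to be binary has more than two distinct values."""


class UnknownMetricError(EntrofuseError):
    """Metric name outside the supported set."""


class UndefinedAUROCError(EntrofuseError):
    """AUROC requested but the ground truth contains a single class."""


class InvalidMetricVectorError(EntrofuseError):
    """Metric vector is empty, all-zero, or contains negative values."""


class WeightError(EntrofuseError):
    """Ensemble weights are inconsistent with the predictions."""


class PlacementError(EntrofuseError):
    """Phantom object placement failed within the retry budget."""
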