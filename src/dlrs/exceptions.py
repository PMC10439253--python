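"""Package-wide exception hierarchy.

Errors are split by phase so the CLI can map them to distinct exit codes:
configuration problems, data/contract violations, and runtime failures.
"""


class DlrsError(Exception):
    """Base class for all package errors."""


class ConfigError(DlrsError):
    """Invalid configuration value or inconsistent config combination."""


class DataError(DlrsError):
    """Input data violates a contract (grids, masks, labels, versions)."""


class GridMismatchError(DataError):
    """Image and mask are not on the same voxel grid."""


class EmptyMaskError(DataError):
    """A region-of-interest mask contains no foreground voxel."""


class TooFewPixelsError(DataError):
    """Too few in-mask pixels for the requested feature computation."""


class DegenerateVolumeError(DataError):
    """A volume dimension is too small for the requested operation."""


class InfeasibleGeometryError(DataError):
    """A synthetic tumor cannot be placed inside the phantom volume."""


class LeakageError(DataError):
    """Train/validation case lists overlap."""


class VersionMismatchError(DataError):
    """Checkpoint feature-dictionary version differs from the feature table."""


class SingleClassError(DataError):
    """A metric that needs both classes was given a single-class label set."""
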