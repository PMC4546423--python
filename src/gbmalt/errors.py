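"""Exception types shared across the pipeline stages."""


class GbmaltError(Exception):
    """Base class for package errors."""


class ConfigurationError(GbmaltError):
    """Invalid acquisition/cohort/pipeline configuration."""


class DomainError(GbmaltError, ValueError):
    """Input outside the physical/mathematical domain of an operation."""


class BoundsError(GbmaltError, IndexError):
    """A region or index exceeds the volume grid."""


class NilVoxelError(GbmaltError):
    """A voxel has no usable baseline signal (signal-loss voxel)."""


class ParameterError(GbmaltError, ValueError):
    """Invalid analysis parameter (e.g. even smoothing window)."""


class TruncationError(GbmaltError):
    """An integration window extends beyond the acquired dynamics."""


class FeatureUndefinedError(GbmaltError):
    """No usable voxels remain after nil exclusion; feature undefined."""


class InputError(GbmaltError, ValueError):
    """Mismatched or wrongly-typed inputs (shapes, map kinds, labels)."""
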