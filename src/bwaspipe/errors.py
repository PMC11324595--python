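"""Exception hierarchy for the pipeline."""


class BwasError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(BwasError):
    """Invalid parameter or configuration value."""


class DataError(BwasError):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file or array does not match its expected layout."""


class AlignmentError(DataError):
    """Grid shapes or affines do not match across inputs."""


class DegenerateDesignError(DataError):
    """A regression design matrix is rank deficient."""


class DegenerateVoxelError(DataError):
    """One or more voxel time series have zero variance."""


class SaturationError(DataError):
    """A correlation of magnitude 1 cannot be Fisher z-transformed."""


class DegenerateTestError(DataError):
    """A neuropsychological test has zero variance across subjects."""


class DegenerateCorrelationError(DataError):
    """A correlation input vector is constant."""


class UndercountError(DataError):
    """Retained links do not cover the significance cutoff."""
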