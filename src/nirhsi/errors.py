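"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers can
discriminate failure modes without string matching.
"""


class NirhsiError(Exception):
    """Base class for all package errors."""


class CubeIOError(NirhsiError):
    """Base class for hyperspectral cube I/O failures."""


class MissingFileError(CubeIOError, FileNotFoundError):
    """Input file does not exist."""


class RaggedPageShapeError(CubeIOError):
    """Multi-page TIFF pages do not all share one shape."""


class BandMismatchError(CubeIOError):
    """Band-axis length disagrees with the wavelength vector."""


class NonFiniteDataError(CubeIOError):
    """Cube contains NaN or Inf voxels."""


class ManifestError(NirhsiError):
    """Cohort manifest violates its contract (duplicate ids, bad labels)."""


class ConfigError(NirhsiError, ValueError):
    """Invalid configuration field."""


class EmptyInputError(NirhsiError, ValueError):
    """An operation received an empty collection it cannot act on."""


class ShapeMismatchError(NirhsiError, ValueError):
    """Array shape incompatible with the model or operation."""


class DegenerateCovarianceError(NirhsiError):
    """Covariance remained singular after shrinkage regularization."""


class AttentionDisabledError(NirhsiError):
    """Attention output requested from a model trained without attention."""


class TrainingDivergedError(NirhsiError):
    """Training produced a non-finite loss; aborted with diagnostics."""


class IdMismatchError(NirhsiError, KeyError):
    """Sample ids in one structure do not cover those in another."""
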