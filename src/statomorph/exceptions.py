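"""Exception hierarchy for statomorph.

All package errors derive from :class:`StatomorphError` so callers can catch
everything the pipeline may raise with a single except clause.
"""


class StatomorphError(Exception):
    """Base class for all statomorph errors."""


class ManifestFormatError(StatomorphError):
    """Manifest file is structurally unreadable (missing columns, bad CSV)."""


class ManifestValidationError(StatomorphError):
    """Manifest parsed but violates a semantic invariant (duplicate
    specimen/face pair, inconsistent species-to-family mapping, unknown
    face token, non-positive scale)."""


class EmptySilhouetteError(StatomorphError):
    """Thresholding produced no foreground pixels."""


class BorderContactError(StatomorphError):
    """Foreground touches the image border; the outline would be clipped."""


class DegenerateShapeError(StatomorphError):
    """Shape too small or collinear to support the requested measurement."""


class NormalizationError(StatomorphError):
    """First-harmonic ellipse is degenerate; coefficients cannot be
    normalized."""


class ParameterError(StatomorphError, ValueError):
    """A function argument is outside its documented domain."""


class AssemblyError(StatomorphError):
    """Feature-matrix assembly failed (e.g. a specimen misses a face)."""


class CanvasError(StatomorphError):
    """Outline does not fit on the requested raster canvas."""


class InsufficientDataError(StatomorphError):
    """Too few observations or groups for the requested statistic."""


class UndefinedSlopeError(StatomorphError):
    """Regression slope undefined (constant predictor within a group)."""
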