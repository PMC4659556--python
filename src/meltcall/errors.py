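"""Exception hierarchy.

Every error raised on a per-well basis carries the plate/well identifier in its
message so a failed 384-well run points at the offending reaction.
"""


class MeltError(Exception):
    """Base class for all meltcall errors."""


class FormatError(MeltError):
    """Input file does not have the expected table shape."""


class ParseError(MeltError):
    """A cell or document could not be parsed (names row/column where known)."""


class EmptyInputError(MeltError):
    """File contained no usable rows."""


class MetadataError(MeltError):
    """Plate-metadata sheet violates its schema (roles, genotype labels, joins)."""


class TraceTooShortError(MeltError):
    """Trace does not span enough grid points for the requested operation."""


class DegenerateCurveError(MeltError):
    """Curve has zero variance (flat melt = failed reaction) or averages to zero."""


class RangeError(MeltError):
    """Requested temperature range does not sufficiently overlap the data."""


class MissingControlsError(MeltError):
    """A plate has no positive-control wells; temperature shifting is impossible."""


class SingularCovarianceError(MeltError):
    """Too few training curves for a genotype to estimate its covariance."""


class ModelVersionError(MeltError):
    """Model file was written with an incompatible schema version."""


class GridMismatchError(MeltError):
    """Curves expected on a common temperature grid are not aligned."""


class UndefinedPosteriorError(MeltError):
    """All class likelihoods vanished; posterior is undefined."""
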