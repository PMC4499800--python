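"""Exception hierarchy for plstraj.

All domain errors derive from :class:`PlstrajError` so callers (and the CLI)
can distinguish expected failures from bugs.
"""


class PlstrajError(Exception):
    """Base class for all plstraj domain errors."""


class FormatError(PlstrajError):
    """Malformed input file: missing/duplicate headers, wrong column layout."""


class SpectraParseError(PlstrajError):
    """A cell that should be numeric is not; carries row/column location."""


class AxisError(PlstrajError):
    """Spectral axis is non-monotone or non-uniform beyond tolerance."""


class ParameterError(PlstrajError, ValueError):
    """An operation parameter is out of its valid range."""


class ShapeError(PlstrajError):
    """Array dimensions are inconsistent with each other or with a model."""


class DegenerateSpectrumError(PlstrajError):
    """A spectrum has zero variance and cannot be SNV-standardized."""


class RankError(PlstrajError):
    """The requested number of latent factors exceeds what the data support."""

    def __init__(self, message: str, max_factors: int | None = None):
        super().__init__(message)
        self.max_factors = max_factors


class DegenerateModelError(PlstrajError):
    """A fitted model explains no response variance (all SS_a = 0)."""


class UndefinedRPDError(PlstrajError):
    """RPD is undefined (zero prediction error)."""


class TrajectoryError(PlstrajError):
    """Every path in a trajectory grid failed."""
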