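"""Exception hierarchy shared across the package."""


class CatmoveError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CatmoveError):
    """A file could not be parsed under its declared format."""


class ValidationError(CatmoveError):
    """An input value violates a documented invariant."""


class InsufficientDataError(CatmoveError):
    """Too few observations to perform the requested operation."""


class DegenerateTrajectoryError(CatmoveError):
    """Cleaning removed so many fixes that no usable trajectory remains."""


class ProjectionError(CatmoveError):
    """The local planar projection is not valid for this trajectory."""


class FitError(CatmoveError):
    """A model failed to fit (non-convergence or rank deficiency)."""


class ConfigError(CatmoveError):
    """A run configuration is invalid."""


class DataError(CatmoveError):
    """Input tables are inconsistent or incomplete."""
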