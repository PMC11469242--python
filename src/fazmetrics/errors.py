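"""Exception hierarchy shared across the package."""


class FazMetricsError(Exception):
    """Base class for all package errors."""


class NoForegroundError(FazMetricsError):
    """Mask contains no usable foreground component."""


class InvalidPolygonError(FazMetricsError):
    """Polygon is degenerate (too few vertices, zero area, collinear...)."""


class ParameterError(FazMetricsError):
    """An argument is outside its documented domain."""


class CentroidOutsideError(FazMetricsError):
    """The polygon centroid falls outside the polygon, violating the
    geometric assumption of the inner-ellipse fit."""


class FitFailedError(FazMetricsError):
    """All optimizer restarts failed to produce a contained ellipse."""


class ConfigError(FazMetricsError):
    """Invalid or incomplete scoring/run configuration."""


class DataError(FazMetricsError):
    """Cohort table does not satisfy the preconditions of a statistic."""


class SpecError(FazMetricsError):
    """Invalid synthetic-shape or cohort specification."""
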