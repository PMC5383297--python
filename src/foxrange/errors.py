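"""Exception types shared across the package."""


class FoxrangeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FoxrangeError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class InsufficientDataError(FoxrangeError, ValueError):
    """Too few fixes / rows to perform the requested operation."""


class DomainError(FoxrangeError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class DegenerateGeometryError(FoxrangeError, ValueError):
    """A polygon has zero area where positive area is required."""


class ZonalStatisticsError(FoxrangeError, ValueError):
    """No raster cell centre (or contour) falls inside the polygon."""


class ZoneAssignmentError(FoxrangeError, ValueError):
    """A centroid lies in no vegetation-zone polygon."""


class UndefinedStatisticError(FoxrangeError, ValueError):
    """A test statistic is undefined (e.g. zero difference variance)."""


class RankDeficiencyError(FoxrangeError, ValueError):
    """The OLS design matrix is rank deficient; names the aliased term."""


class InfiniteLikelihoodError(FoxrangeError, ValueError):
    """RSS is exactly zero, so the Gaussian log-likelihood diverges."""


class NoResidentsError(FoxrangeError, RuntimeError):
    """The residency filter left an empty cohort."""


class SchemaError(FoxrangeError, ValueError):
    """An input table is missing required columns or has unparseable rows."""
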