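"""Exception hierarchy.

Three branches map onto the CLI exit codes: configuration problems (exit 2),
data/validation problems (exit 3), and numerical/domain problems (exit 4).
"""


class IsoNicheError(Exception):
    """Base class for all package errors."""


class ConfigError(IsoNicheError):
    """Invalid configuration: bad scenario, chain settings, draw counts, ..."""


class DataError(IsoNicheError):
    """Invalid or insufficient input data."""


class SchemaError(DataError):
    """A required column is missing from a tabular input."""


class ParseError(DataError):
    """A cell could not be parsed (reports the offending row)."""


class ValidationError(DataError):
    """A record violates a domain-type invariant."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class BaselineError(DataError):
    """The baseline taxon is absent where it is needed."""


class NumericalError(IsoNicheError):
    """Numerical/domain failure (saturation, degenerate geometry, ...)."""


class DomainError(NumericalError):
    """An argument lies outside the mathematical domain of an operation."""


class SaturationError(NumericalError):
    """A d15N value at or above the saturating limit: trophic position undefined."""


class DegenerateEllipseError(NumericalError):
    """Singular covariance: the standard ellipse is not defined."""
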