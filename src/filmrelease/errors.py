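"""Exception hierarchy for filmrelease."""


class FilmReleaseError(Exception):
    """Base class for all filmrelease errors."""


class DomainError(FilmReleaseError, ValueError):
    """An argument lies outside the physical or mathematical domain."""


class DegenerateGeometryError(DomainError):
    """A layered-film decomposition has no physical solution."""


class NonIdentifiableError(FilmReleaseError, ValueError):
    """The data carry no information about the parameter being fitted."""


class ConvergenceError(FilmReleaseError, RuntimeError):
    """An iterative computation failed to converge within its budget."""


class ConfigurationError(FilmReleaseError, ValueError):
    """Invalid options or run configuration."""


class ParseError(FilmReleaseError, ValueError):
    """A delimited input file could not be parsed."""


class DegenerateDataError(FilmReleaseError, ValueError):
    """Grouped data are degenerate (e.g. zero variance everywhere)."""
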