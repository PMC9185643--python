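"""Exception hierarchy for agrisurvey.

All toolkit-specific failures derive from :class:`AgrisurveyError` so callers
can catch one base class; most also derive from the matching builtin
(``ValueError`` for bad inputs) so they behave idiomatically.
"""


class AgrisurveyError(Exception):
    """Base class for all agrisurvey errors."""


class InvalidInputError(AgrisurveyError, ValueError):
    """An argument violates a documented precondition."""


class PolarRegionError(InvalidInputError):
    """Longitude correction requested too close to a pole (|lat| >= 89.9 deg)."""


class EmptyRouteError(AgrisurveyError, ValueError):
    """A route operation produced or received zero waypoints/tiles."""


class UnreachableWaypointError(AgrisurveyError, ValueError):
    """A waypoint cannot be visited and returned from within the range budget."""


class MissingBandError(AgrisurveyError, LookupError):
    """No cube band lies within tolerance of a required wavelength."""


class UnknownIndexError(AgrisurveyError, KeyError):
    """Requested vegetation index is not in the registry."""


class DegenerateFitError(AgrisurveyError, ValueError):
    """Empirical-line fit impossible (fewer than 2 panels or identical DNs)."""


class UnitsError(AgrisurveyError, ValueError):
    """Cube units are wrong for the requested operation (DN vs reflectance)."""


class ParseError(AgrisurveyError, ValueError):
    """A mission or cube file could not be parsed.

    Carries ``line`` (1-based) when the failure is tied to a specific line.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InvalidRulesError(AgrisurveyError, ValueError):
    """Classification rules overlap or are malformed."""


class InvalidSpecError(AgrisurveyError, ValueError):
    """A scene/report specification is internally inconsistent."""
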