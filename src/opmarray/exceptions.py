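"""Exception and warning types shared across the package."""


class OpmArrayError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OpmArrayError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class SurfaceError(OpmArrayError):
    """A surface could not be built (e.g. the cut plane removes every face)."""


class GeometryError(OpmArrayError):
    """Sensor/source geometry violates the forward-model preconditions."""


class SingularPointError(OpmArrayError):
    """An irregular (internal) harmonic was evaluated at its singular point."""


class EmptyLeadFieldError(OpmArrayError):
    """Source filtering removed every column of a lead field."""


class UndefinedRatioError(OpmArrayError):
    """An SNIR ratio is undefined (zero triaxial attenuation factor)."""


class DegenerateOrientationWarning(UserWarning):
    """The tangential-axis rule hit an exact pole; the documented fallback applies."""
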