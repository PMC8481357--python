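"""Exception hierarchy shared across zorbkit."""


class ZorbkitError(Exception):
    """Base class for all zorbkit errors."""


class ArgumentError(ZorbkitError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(ZorbkitError):
    """A configuration value is missing or inconsistent."""


class GeometryError(ZorbkitError):
    """Bodies overlap, touch the drop wall, or otherwise break the geometry."""


class DegenerateGeometryError(ZorbkitError):
    """A local node arrangement makes the GMLS Gram matrix rank deficient."""

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(message)
        self.condition_number = condition_number


class SolverError(ZorbkitError):
    """The global linear solve failed or did not converge."""


class AdaptiveError(ZorbkitError):
    """Adaptive refinement exhausted its iteration budget."""

    def __init__(self, message: str, last_estimate: float = float("nan")):
        super().__init__(message)
        self.last_estimate = last_estimate


class IntegrationError(ZorbkitError):
    """Boundary quadrature could not be carried out."""


class FormatError(ZorbkitError):
    """An input file is not in the expected format."""


class ConsistencyError(ZorbkitError):
    """Quantities computed under incompatible normalizations were combined."""
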