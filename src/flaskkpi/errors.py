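"""Exception hierarchy for flaskkpi."""


class FlaskKPIError(Exception):
    """Base class for all flaskkpi errors."""


class FormatError(FlaskKPIError):
    """A sensor log or recipe file does not have the expected structure."""


class TraceValidationError(FlaskKPIError):
    """A signal trace violates its invariants (ordering, finiteness, length)."""


class RecipeError(FlaskKPIError):
    """A recipe file fails schema validation."""


class ConfigurationError(FlaskKPIError):
    """Required physical metadata (kLa, c*) is missing or inconsistent."""


class ParameterError(FlaskKPIError):
    """An algorithm parameter is out of range for the given trace."""


class DetectionError(FlaskKPIError):
    """The exponential-phase detector could not produce a valid window.

    Carries a ``diagnostics`` dict with the anchors and intermediate state
    that were available when detection failed.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SimulationError(FlaskKPIError):
    """The batch simulator became unstable (e.g. substrate driven negative)."""


class ComputationError(FlaskKPIError):
    """A KPI cannot be computed from the supplied inputs."""
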