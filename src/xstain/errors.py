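"""Exception hierarchy for the staining-analysis pipeline."""


class XStainError(Exception):
    """Base class for all package errors."""


class InvalidGridError(XStainError):
    """A depth or time grid is not strictly increasing or is otherwise unusable."""


class GeometryError(XStainError):
    """Geometry is degenerate or a footprint falls outside the image."""


class StageError(XStainError):
    """An intensity profile was passed to an operation at the wrong pipeline stage."""


class WindowError(XStainError):
    """A depth/time averaging window is empty or not covered by the data grid."""


class RegistrationError(XStainError):
    """Image registration is undefined (e.g. a textureless frame)."""


class IntegrationError(XStainError):
    """The PDE integrator failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class FitError(XStainError):
    """A least-squares fit failed or has no degrees of freedom."""


class DegenerateStandardizationError(XStainError):
    """Standardization denominator is non-positive."""
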