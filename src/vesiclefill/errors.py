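"""Exception hierarchy shared across the package."""


class VesicleFillError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(VesicleFillError, ValueError):
    """A parameter violates a documented precondition."""


class DegenerateTraceError(VesicleFillError):
    """A trace has no usable dynamic range (e.g. constant fluorescence)."""


class OutOfRangeError(VesicleFillError, ValueError):
    """A value lies outside the invertible/calibrated range of a sensor map."""


class SaturationError(OutOfRangeError):
    """A ratio lies at or beyond sensor saturation; carries the usable bound."""

    def __init__(self, message: str, bound_mM: float | None = None):
        super().__init__(message)
        self.bound_mM = bound_mM


class CalibrationIdentifiabilityError(VesicleFillError):
    """The calibration design is rank deficient for the requested fit."""


class ConfigError(VesicleFillError):
    """Run configuration failed validation; message lists all failures."""


class IntegrationError(VesicleFillError):
    """The flux-model integrator could not complete within step limits."""
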