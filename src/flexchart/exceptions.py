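"""Exception hierarchy for flexchart."""


class FlexchartError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FlexchartError):
    """A configuration problem: missing columns, bad option values, empty family list."""


class DataValidationError(FlexchartError):
    """Input data violate an invariant (non-positive flexion, unparseable dates, ...)."""


class ConvergenceError(FlexchartError):
    """Model fitting failed to converge; carries the global-deviance trace."""

    def __init__(self, message, deviance_trace=None):
        super().__init__(message)
        self.deviance_trace = list(deviance_trace) if deviance_trace is not None else []


class ChartError(FlexchartError):
    """Reference-chart construction failed (e.g. non-monotone centile curves)."""


class SerializationError(FlexchartError):
    """A model file could not be read or has an incompatible version."""
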