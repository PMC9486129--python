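"""Exception types shared across the package."""


class Tsh2BindError(Exception):
    """Base class for package-specific errors."""


class ParameterError(Tsh2BindError, ValueError):
    """A rate constant, concentration or configuration value is invalid."""


class SteadyStateError(Tsh2BindError, RuntimeError):
    """Steady state could not be reached within the extension limit."""


class EstimationError(Tsh2BindError, RuntimeError):
    """A fit failed to converge or the data are degenerate."""


class SchemaError(Tsh2BindError, ValueError):
    """An input file does not conform to the expected column schema."""
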