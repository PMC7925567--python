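"""Exception hierarchy shared across the package."""


class EvpairError(Exception):
    """Base class for all package errors."""


class FormatError(EvpairError):
    """Malformed input file (ragged alignment, undecodable dialect, ...)."""


class EmptyInputError(EvpairError):
    """An input that must contain data is empty."""


class ParameterError(EvpairError):
    """A parameter value outside its documented domain."""


class DegenerateInputError(EvpairError):
    """Structurally valid input on which the operation is undefined."""


class ConvergenceError(EvpairError):
    """Optimizer failed to reach tolerance within the iteration cap."""

    def __init__(self, message: str, grad_norm: float | None = None):
        super().__init__(message)
        self.grad_norm = grad_norm


class TrainingError(EvpairError):
    """Classifier training impossible (single class, all features dropped)."""


class ConfigurationError(EvpairError):
    """Missing or inconsistent pipeline configuration."""
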