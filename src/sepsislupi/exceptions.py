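"""Exception hierarchy shared across the package."""


class SepsisLupiError(Exception):
    """Base class for all package errors."""


class ParameterError(SepsisLupiError, ValueError):
    """A tunable parameter is outside its valid range."""


class InputError(SepsisLupiError, ValueError):
    """An input object violates a precondition."""


class ConfigurationError(SepsisLupiError, ValueError):
    """A configuration object is malformed."""


class TrainingError(SepsisLupiError, RuntimeError):
    """Model fitting cannot proceed (e.g. a single-class training set)."""


class EvaluationError(SepsisLupiError, RuntimeError):
    """An evaluation step failed (e.g. every grid candidate errored)."""
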