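"""Exception hierarchy for model loading, validation and evaluation."""


class CEAError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CEAError):
    """A parameter, payoff or distribution specification violates its invariants."""


class InfeasibleMomentsError(ValidationError):
    """The stated mean and SD cannot be matched by the requested family."""


class ConfigError(CEAError):
    """The model configuration file is malformed or internally inconsistent."""


class EvaluationError(CEAError):
    """Tree evaluation failed, e.g. an unresolved parameter reference."""
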