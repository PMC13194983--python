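"""Exception hierarchy."""


class RelaxciderError(Exception):
    """Base class for package errors."""


class InvalidParameterError(RelaxciderError, ValueError):
    """A model parameter violates its domain (negative rate, tau_c <= 0, ...)."""


class FitError(RelaxciderError):
    """A least-squares fit could not be performed or did not converge."""


class DataError(RelaxciderError):
    """Input data violate a precondition (too few points, negative rates, ...)."""


class ConfigurationError(RelaxciderError):
    """Missing or inconsistent configuration (e.g. no tau_c supplied for a CSA fit)."""


class PairingError(RelaxciderError):
    """Two profiles share no usable field grid for subtraction."""


class PlanValidationError(RelaxciderError):
    """A subtraction-plan pair differs in more than one composition feature."""


class DegenerateModelError(RelaxciderError):
    """The decay model is degenerate for the given acquisition parameters."""
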