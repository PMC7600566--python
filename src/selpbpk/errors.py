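"""Exception hierarchy shared across the package."""


class SelPbpkError(Exception):
    """Base class for all package errors."""


class InputError(SelPbpkError, ValueError):
    """A caller-supplied numeric value is out of its physical domain."""


class ConfigurationError(SelPbpkError, ValueError):
    """A model is assembled from an inconsistent or incomplete configuration."""


class ValidationError(SelPbpkError, ValueError):
    """A domain invariant is violated (e.g. infeasible clearances)."""


class SolverError(SelPbpkError, RuntimeError):
    """ODE integration failed; carries a diagnostic message and state snapshot."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
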