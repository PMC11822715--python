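"""Exception hierarchy shared across the pipeline."""


class ProtospikeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ProtospikeError, ValueError):
    """A file does not follow the expected on-disk layout."""


class FitFailureError(ProtospikeError, RuntimeError):
    """A model fit did not converge or the problem is degenerate.

    Carries optional diagnostics (best-so-far parameters, solver message).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IntegrationError(ProtospikeError, RuntimeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message, t_failure=None):
        super().__init__(message)
        self.t_failure = t_failure
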