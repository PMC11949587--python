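"""Exception hierarchy for the hopfnet pipeline."""


class HopfnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HopfnetError, ValueError):
    """A file or matrix does not match the expected layout."""


class ValidationError(HopfnetError, ValueError):
    """A value violates a type invariant (negative weight, bad band, ...)."""


class CapabilityError(HopfnetError, ValueError):
    """The requested operation needs data the inputs do not carry."""


class IntegrationError(HopfnetError, RuntimeError):
    """The ODE solver failed or produced non-finite state.

    ``t_fail`` carries the integration time at which the failure occurred.
    """

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class DegenerateSignalError(HopfnetError, ValueError):
    """A signal is degenerate for the requested analysis (e.g. all zero)."""


class UndefinedCorrelationError(HopfnetError, ValueError):
    """The Pearson objective is undefined (zero variance on one side)."""


class GenerationError(HopfnetError, RuntimeError):
    """Synthetic-data generation failed (e.g. connectivity retry bound hit)."""
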