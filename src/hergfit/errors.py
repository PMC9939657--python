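"""Exception hierarchy."""


class HergFitError(Exception):
    """Base class for all package errors."""


class SimulationInfeasibleError(HergFitError):
    """Raised when a parameter set cannot be simulated.

    Covers rate-law exponent overflow and ODE-solver breakdown; the
    fitter's failure classification catches this to mark a fit as
    ``failed`` rather than ``local_minimum``.
    """


class ProtocolParseError(HergFitError):
    """Malformed protocol CSV (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SamplerError(HergFitError):
    """Prior rejection budget exceeded or MCMC stall."""


class DatasetError(HergFitError):
    """Dataset generation/IO failure."""


class TrainingError(HergFitError):
    """Regressor training diverged."""


class ModelFormatError(HergFitError):
    """Saved-model file is truncated, corrupt, or version-incompatible."""
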