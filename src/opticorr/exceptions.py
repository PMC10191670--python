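"""Exception hierarchy for opticorr."""


class OpticorrError(Exception):
    """Base class for all opticorr errors."""


class ValidationError(OpticorrError, ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Raised when an input is too small or too poor to process (e.g. fewer
    than four spectral samples)."""


class SamplingError(OpticorrError):
    """Raised when the PSF grid cannot contain the simulated blur.

    Carries ``contained_energy`` (fraction of PSF energy inside the grid) so
    callers can decide how much to enlarge ``grid_px`` or the field extent.
    """

    def __init__(self, message: str, contained_energy: float | None = None):
        super().__init__(message)
        self.contained_energy = contained_energy


class OptimizationError(OpticorrError):
    """Raised when the image optimizer diverges; carries the loss trace."""

    def __init__(self, message: str, loss_trace=None):
        super().__init__(message)
        self.loss_trace = list(loss_trace) if loss_trace is not None else []
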