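"""Package-specific exceptions."""


class MemconsolError(Exception):
    """Base class for package errors."""


class AlignmentError(MemconsolError, ValueError):
    """A schedule window edge does not fall on the integration step grid."""


class NumericError(MemconsolError, RuntimeError):
    """The integrator produced a non-finite or substantially negative state."""

    def __init__(self, message: str, time_s: float | None = None,
                 component: str | None = None):
        super().__init__(message)
        self.time_s = time_s
        self.component = component


class EquilibrationError(MemconsolError, RuntimeError):
    """Relaxation to the basal fixed point did not reach tolerance."""

    def __init__(self, message: str, residual: float | None = None,
                 component: str | None = None):
        super().__init__(message)
        self.residual = residual
        self.component = component
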