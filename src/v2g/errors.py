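"""Exception hierarchy."""


class V2GError(Exception):
    """Base class for all package errors."""


class InvalidDeformationError(V2GError):
    """Deformation state is kinematically inadmissible (non-SPD C, det F <= 0...)."""


class ParameterRangeError(V2GError):
    """Material parameters or stretch range produce overflow / inadmissible energy."""


class ConvergenceError(V2GError):
    """An iterative solver failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message, best=None, trace=None):
        super().__init__(message)
        self.best = best
        self.trace = trace


class CalibrationError(V2GError):
    """A calibration target is unreachable within the admissible bounds."""
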