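"""Exception types shared across the package."""


class PumpProbeError(Exception):
    """Base class for package errors."""


class InvalidStateError(PumpProbeError, ValueError):
    """A model state violates its invariants (e.g. negative concentration)."""


class IntegrationError(PumpProbeError, RuntimeError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_t: float | None = None):
        super().__init__(message)
        self.last_t = last_t


class NoSteadyStateError(PumpProbeError, ValueError):
    """Net production exceeds uptake capacity: no finite extracellular steady state."""


class GeometryError(PumpProbeError, ValueError):
    """Invalid cell geometry (e.g. length shorter than diameter)."""


class CalibrationError(PumpProbeError, ValueError):
    """Fluorescence calibration cannot be computed from the given records."""


class InvalidTraceError(PumpProbeError, ValueError):
    """A photobleaching trace cannot yield a FRET efficiency."""


class BracketError(PumpProbeError, ValueError):
    """A root/half-max point is not bracketed by the supplied grid."""


class FitFailureError(PumpProbeError, RuntimeError):
    """All optimization starts failed to converge."""
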