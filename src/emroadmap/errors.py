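"""Exception types shared across the package."""


class EmroadmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EmroadmapError, ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class GeometryError(EmroadmapError):
    """Raised when a geometric construction fails (self-intersection, non-cappable mesh...)."""


class ConvergenceError(EmroadmapError):
    """Raised when the quasi-static solver fails to reach equilibrium.

    Carries the energy trace of the failed solve for post-mortem inspection.
    """

    def __init__(self, message, energy_trace=None, diagnostics=None):
        super().__init__(message)
        self.energy_trace = energy_trace if energy_trace is not None else []
        self.diagnostics = diagnostics


class FrameMismatchError(EmroadmapError, ValueError):
    """Raised when point sets expressed in different frames are compared."""
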