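"""Exception types raised across the package."""


class GtenetError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(GtenetError):
    """Malformed input (non-square adjacency, missing positions, NaNs...)."""


class ConvergenceError(GtenetError):
    """An iterative procedure failed to reach its target.

    Attributes carry the best state achieved so the caller can decide
    whether to proceed with it.
    """

    def __init__(self, message, best=None, trace=None):
        super().__init__(message)
        self.best = best
        self.trace = trace


class TuningError(ConvergenceError):
    """Synaptic-weight auto-tuning did not reach the target burst rate."""


class IntegrationError(GtenetError):
    """The spiking simulation blew up numerically."""
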