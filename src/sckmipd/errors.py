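"""Package exception hierarchy."""


class SckMipdError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SckMipdError, ValueError):
    """An argument violates a documented precondition or invariant."""


class CalibrationError(SckMipdError):
    """A requested calibration target is infeasible."""


class SimulationError(SckMipdError):
    """ODE integration failed; carries the offending time span in args."""


class EstimationError(SckMipdError):
    """Individual parameter estimation failed for every start."""


class SamplerError(SckMipdError):
    """MCMC sampler failed to reach a workable acceptance rate."""


class DatasetError(SckMipdError):
    """A dataset file violates the event-record dialect."""


class InsufficientDataError(SckMipdError):
    """Not enough pooled data to compute the requested summary."""
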