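"""Exception hierarchy for kinens."""


class KinensError(Exception):
    """Base class for all kinens errors."""


class FluxDomainError(KinensError):
    """A flux was evaluated outside its domain (e.g. 0^negative)."""


class DimensionError(KinensError):
    """Array shapes inconsistent with the model structure."""


class SimulationError(KinensError):
    """ODE integration failed or the state left the finite domain.

    Attributes
    ----------
    last_valid_time : float or None
        Last time point at which the integrator held a finite state.
    """

    def __init__(self, message, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class SmoothingError(KinensError):
    """Smoother could not be fitted (too few points, all candidates failed)."""


class StructuralError(KinensError):
    """No valid independent/dependent flux split exists."""


class RankDeficiencyError(KinensError):
    """Regression design matrix is rank deficient (collinear profiles)."""


class FeasibilityError(KinensError):
    """No feasible parameter point found under the given bounds."""
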