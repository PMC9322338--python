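"""Exception hierarchy for hp13c.

All validation failures raise :class:`ValidationError` (a ``ValueError``) so
callers can catch one type; the narrower subclasses exist where the *reason*
matters to control flow (e.g. routing a 90 degree pulse to the discrete RF
pathway instead of the continuous-rate formula).
"""


class HP13CError(Exception):
    """Base class for all package errors."""


class ValidationError(HP13CError, ValueError):
    """An input violated a documented precondition."""


class SaturatingPulseError(ValidationError):
    """A 90 degree flip was passed to the continuous effective-rate formula.

    cos(90 deg) = 0, so the per-TR loss cannot be folded into a continuous
    rate.  Use the discrete RF event pathway (``rf_event`` /
    ``simulate_pools``), which is exact at all flips including saturation.
    """


class SimulationDivergedError(HP13CError):
    """The simulated magnetization became non-finite."""


class InfeasibleConstraintError(HP13CError):
    """No grid point satisfies the requested SNR-retention constraints."""

    def __init__(self, message: str, binding: list[str] | None = None):
        super().__init__(message)
        #: names of the constraints that excluded every candidate point
        self.binding = binding or []


class DataQualityError(HP13CError):
    """Input data failed a quality gate (e.g. mostly negative signal)."""


class InferenceImpossibleError(HP13CError):
    """Too few complete pairs remain for paired inference."""
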