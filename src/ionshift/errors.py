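"""Exception hierarchy for the simulator."""


class IonShiftError(Exception):
    """Base class for all package errors."""


class StructuralError(IonShiftError):
    """Morphology graph is not a rooted tree (cycle, disconnection, bad parent)."""


class ValidationError(IonShiftError):
    """Invalid geometry or parameter value (e.g. non-positive radius)."""


class ConfigurationError(IonShiftError):
    """Inconsistent model configuration (unlabeled region, unknown mechanism...)."""


class IntegrationError(IonShiftError):
    """Numerical failure during time stepping (singular solve, NaN state)."""


class HomeostasisError(IonShiftError):
    """An ion concentration was driven to zero or below."""


class StateCorruptionError(IonShiftError):
    """A state variable left its admissible range (occupancy outside [0,1])."""


class CalibrationError(IonShiftError):
    """Resting-state balance is infeasible (negative required conductance)."""


class FittingError(IonShiftError):
    """A parameter fit failed to converge."""
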