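"""Exception and warning types shared across the package."""


class GradientPNError(Exception):
    """Base class for all package errors."""


class StructuralError(GradientPNError):
    """A marking or step refers to an identifier the net does not declare,
    or the net itself violates a structural invariant."""


class EnablingError(GradientPNError):
    """A step was executed at a marking where it is not enabled."""


class ParameterError(GradientPNError, ValueError):
    """A physical or numerical parameter is out of its admissible range."""


class InputError(GradientPNError, ValueError):
    """An input profile, field or file content is invalid."""


class ConfigError(GradientPNError):
    """A configuration file is missing keys or carries invalid values."""


class NumericError(GradientPNError):
    """A reference solver failed its stability or convergence check."""


class SteadyStateTimeout(GradientPNError):
    """Steady state was not reached within the configured cycle cap."""


class ConflictWarning(UserWarning):
    """Two transitions (or extra occurrences of one) competed for the same
    tokens while building a maximal step; the greedy resolution was used."""


class AccuracyWarning(UserWarning):
    """An integer arc weight rounded to zero, or a profile lost monotonicity;
    the computation proceeds but accuracy is degraded."""
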