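"""Exception and warning types used across the package."""


class CNCBError(Exception):
    """Base class for errors raised by this package."""


class NumericalError(CNCBError):
    """A computation produced non-finite probabilities or diverged."""


class CalibrationError(CNCBError):
    """A requested confidence-level proportion is numerically unreachable."""


class UndefinedRateError(CNCBError):
    """A Type 2 rate was requested on a zero-probability conditioning set."""


class EfficiencyRangeError(CNCBError):
    """Target Type 2 behaviour is outside the range attainable by the
    boost-1 observer family (below chance or above its frontier)."""


class ModelMisconfigurationError(CNCBError):
    """Model configuration violates a structural assumption (e.g. the
    evidence-to-probability map is not monotone on the evaluation grid)."""


class DegenerateStimulusWarning(UserWarning):
    """A stimulus strength coincides with the sensory criterion, so
    correctness of the decision is ill-defined (probability 0.5)."""
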