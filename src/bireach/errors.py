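"""Exception hierarchy for bireach.

All package-specific failures derive from :class:`BireachError`, so callers
(and the CLI) can distinguish user/data errors from genuine bugs.
"""


class BireachError(Exception):
    """Base class for all bireach errors."""


class InvalidParameterError(BireachError, ValueError):
    """A configuration value or operation argument is out of its valid domain."""


class SimulationError(BireachError):
    """Numerical failure (NaN/divergence) while integrating a trial."""


class DetectionError(BireachError):
    """Movement onset/offset could not be located in a speed series."""


class UndefinedAngleError(BireachError):
    """Angular error requested for a point coincident with the home position."""


class DegenerateTrialError(BireachError):
    """A trial has no usable movement (e.g. zero path length)."""


class MissingBaselineError(BireachError):
    """A participant/hand lacks the baseline block needed for correction."""


class BinningError(BireachError):
    """A block is too short for the requested bin size."""


class ResamplingError(BireachError):
    """Too few samples between onset and offset to resample."""


class IncompleteDesignError(BireachError):
    """A subject is missing one or more within-subject cells."""


class UndefinedEffectSizeError(BireachError):
    """Effect-size denominator is zero (no variance anywhere)."""
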