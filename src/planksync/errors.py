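"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PlanksyncError`, so callers (CLI,
analysis drivers) can distinguish pipeline failures from programming errors.
"""


class PlanksyncError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PlanksyncError):
    """Malformed input file (bad header, unparseable row, duplicate timestamp)."""


class ValidationError(PlanksyncError):
    """A series or parameter set violates a domain invariant."""


class AlignmentError(PlanksyncError):
    """Two series share no common timestamps or are not on the same timeline."""


class ImputationError(PlanksyncError):
    """A calendar-month slice is entirely missing; interpolation is impossible."""


class DomainError(PlanksyncError):
    """A value entering a denominator (abundance) is non-positive."""


class PhaseUndefinedError(PlanksyncError):
    """Fewer than two oscillation maxima; no phase can be assigned."""


class SynchronizationUndefinedError(PlanksyncError):
    """Two phase series share no common domain; PLI is undefined."""


class SimulationError(PlanksyncError):
    """Forward simulation produced a non-viable (extinct) trajectory."""


class ConfigError(PlanksyncError):
    """Invalid or missing key in a pipeline configuration file."""
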