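"""Exception hierarchy for the dynpet pipeline.

Every stage raises a subclass of :class:`DynpetError` so that the pipeline
driver can attribute a failure to its stage and persist partial output.
"""


class DynpetError(Exception):
    """Base class for all dynpet errors."""


class FormatError(DynpetError):
    """An input file does not have the expected structure (dimensions, dtype)."""


class ScheduleError(DynpetError):
    """A frame-timing table violates the schedule invariants."""


class NamingError(DynpetError):
    """A VOI label map contains labels absent from the names table."""


class ExtractionError(DynpetError):
    """A requested VOI is empty or missing, so a curve cannot be extracted."""


class PhantomSpecError(DynpetError):
    """A phantom specification is inconsistent (e.g. overlapping regions)."""


class WindowError(DynpetError):
    """A Patlak window cannot be constructed on the given schedule."""


class FitError(DynpetError):
    """A model fit could not be completed."""


class ParameterError(DynpetError, ValueError):
    """An operation received an out-of-range parameter."""
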