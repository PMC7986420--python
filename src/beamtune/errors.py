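"""Exception hierarchy.

All beamtune errors derive from :class:`BeamtuneError` so callers can catch the
package's failures with a single ``except`` clause while still letting the
specific classes double as ``ValueError`` where that is the natural contract.
"""


class BeamtuneError(Exception):
    """Base class for all beamtune errors."""


class DomainError(BeamtuneError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class InfeasibleOpticsError(DomainError):
    """A phase-space parameter triple violates the ellipse feasibility bound."""


class ExtractionError(BeamtuneError, ValueError):
    """A curve metric (R80, BPW, FWHM) cannot be extracted from the data."""


class MeasurementFormatError(BeamtuneError, ValueError):
    """A measurement file is malformed; the message names file and line."""


class StageOrderError(BeamtuneError, RuntimeError):
    """A pipeline stage was invoked before its prerequisite artifacts exist."""
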