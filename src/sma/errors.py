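"""Exception hierarchy for the SMA analysis pipeline.

Every stage raises a subclass of :class:`SmaError` so callers (and the batch
CLI) can distinguish analysis failures from programming errors.
"""


class SmaError(Exception):
    """Base class for all analysis errors."""


class ValidationError(SmaError, ValueError):
    """An input violated a documented precondition or invariant."""


class FovNotFound(SmaError):
    """No plausible ultrasound field of view could be segmented."""


class ApoNotFound(SmaError):
    """Fewer than two aponeuroses could be registered.

    The message always suggests the two documented remedies: cropping the
    image manually, or raising the tubeness sigma.
    """


class RoiTooSmall(SmaError):
    """The requested ROI height is below the minimum usable size."""


class NoFascicleOrientation(SmaError):
    """No ROI produced a valid dominant orientation."""


class NoIntersection(SmaError):
    """The composite fascicle line does not intersect the superficial
    aponeurosis (parallel lines)."""
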