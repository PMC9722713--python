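"""Exception hierarchy for the digitisation pipeline.

Every pipeline failure raises a subclass of :class:`DigitisationError` whose
``stage`` attribute names the failing step, so callers (and the CLI) can
report where a record was lost.
"""


class DigitisationError(Exception):
    """Base class for all pipeline failures."""

    stage = "pipeline"


class EntirelyRedactedError(DigitisationError):
    """Every row of the image is black: nothing left to digitise."""

    stage = "preprocess"


class NoBaselinesError(DigitisationError):
    """No near-horizontal line survived the width/merge constraints."""

    stage = "layout"


class LeadNameDetectionError(DigitisationError):
    """Not a single lead-name string was recognised anywhere on the page."""

    stage = "leadfind"


class AnchorGeometryError(DigitisationError):
    """Horizontal anchors produced an overlapping or inverted crop span."""

    stage = "leadfind"


class EmptyLeadError(DigitisationError):
    """A cropped lead contained no ink to digitise."""

    stage = "extract"

    def __init__(self, label: str, message: str | None = None):
        self.label = label
        super().__init__(message or f"empty lead: {label!r}")


class IncompleteRecordError(DigitisationError):
    """Missing or duplicated lead labels when assembling a record."""

    stage = "extract"


class CalibrationError(DigitisationError):
    """Non-positive reference width or otherwise impossible calibration."""

    stage = "extract"
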