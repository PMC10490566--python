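"""Exception hierarchy for the pressure-mat toolkit."""


class MabumatError(Exception):
    """Base class for all package-specific errors."""


class FrameFormatError(MabumatError):
    """Malformed frame file: bad header, non-integer cell, or out-of-range value."""


class ShapeMismatchError(FrameFormatError):
    """Frame shape disagrees with the sensor configuration or its own header."""


class ZeroPressureError(MabumatError):
    """A center of pressure was requested for a frame carrying no load."""


class EmptyHalfError(ZeroPressureError):
    """A half-frame contains no loaded cells: no foot is present."""


class DegenerateBlobError(MabumatError):
    """A foot blob is too small or collinear to define a principal axis."""


class MissingFootError(MabumatError):
    """A foot required for a stance-level computation could not be detected."""


class StanceOffMatError(MabumatError):
    """A simulated stance does not fit on the sensing surface."""


class CalibrationError(MabumatError):
    """Calibration frame failed the entry-stance criteria; user must redo it.

    Carries the :class:`~mabumat.calibration.CriteriaReport` so callers can
    tell the user which of the five criteria failed.
    """

    def __init__(self, report):
        self.report = report
        failed = ", ".join(report.failed()) or "unknown"
        super().__init__(f"calibration stance invalid; failed criteria: {failed}")
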