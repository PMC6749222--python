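"""Exception hierarchy for the verification pipeline."""


class HandVeinError(Exception):
    """Base class for all package errors."""


class ParameterError(HandVeinError, ValueError):
    """An operation received a parameter outside its documented range."""


class RenderError(HandVeinError):
    """The synthetic hand could not be placed fully inside the frame."""


class SegmentationError(HandVeinError):
    """Segmentation produced no usable foreground object."""


class HandDetectionError(HandVeinError):
    """The silhouette does not expose five finger candidates."""


class MeasurementError(HandVeinError):
    """A measurement axis left the silhouette; the feature is undefined."""


class EnrollmentError(HandVeinError):
    """Template construction needs at least two enrollment captures."""


class EmptySetError(HandVeinError, ValueError):
    """Point-set distances are undefined for empty sets."""


class DegenerateBatchError(HandVeinError):
    """Min-max normalization is undefined when all scores coincide."""


class EvaluationError(HandVeinError):
    """The comparison table lacks a genuine or impostor class."""
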