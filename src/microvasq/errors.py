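"""Exception hierarchy for the microvasq pipeline."""


class MicrovasqError(Exception):
    """Base class for all package errors."""


class CalibrationError(MicrovasqError):
    """Missing or invalid physical field-of-view metadata."""


class GeometryError(MicrovasqError):
    """Invalid resize/crop/registration request."""


class PreprocessError(MicrovasqError):
    """Invalid preprocessing parameters or input."""


class SegmentationError(MicrovasqError):
    """Segmentation-chain failure (e.g. degenerate histogram)."""


class QuantifyError(MicrovasqError):
    """Density / fractal quantification failure."""


class StatsError(MicrovasqError):
    """Invalid input to a statistical comparison."""


class PipelineError(MicrovasqError):
    """A pipeline stage failed; the message names the stage."""
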