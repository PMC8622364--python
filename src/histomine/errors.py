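"""Exception types shared across the pipeline."""


class HistomineError(Exception):
    """Base class for all package errors."""


class SlideBoundsError(HistomineError, ValueError):
    """A region read extends outside the slide."""


class SlideIOError(HistomineError, IOError):
    """A slide or annotation file could not be read."""


class DegenerateHistogramError(HistomineError, ValueError):
    """Otsu thresholding on a histogram with fewer than two populated levels."""


class AnnotationFormatError(HistomineError, ValueError):
    """A GeoJSON annotation file violates the expected schema."""


class GeometryError(HistomineError, ValueError):
    """Degenerate or out-of-bounds geometry (zero-area polygon, tile > slide...)."""


class SamplingError(HistomineError, RuntimeError):
    """Tile sampling could not satisfy its contract (e.g. no candidate tiles)."""


class ConfigurationError(HistomineError, ValueError):
    """Invalid or inconsistent run configuration."""


class UndefinedMetricError(HistomineError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


class ModelError(HistomineError, ValueError):
    """Model construction, checkpoint, or freeze-policy failure."""
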