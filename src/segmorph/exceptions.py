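"""Exception hierarchy for segmorph."""


class SegmorphError(Exception):
    """Base class for all segmorph errors."""


class InvalidArgumentError(SegmorphError, ValueError):
    """A function argument violates a documented precondition."""


class SegmentationError(SegmorphError):
    """Foreground segmentation of a larval image failed (no body, or several)."""


class OrientationError(SegmorphError):
    """The anterior end of the larva could not be resolved."""


class DetectionError(SegmorphError):
    """Fewer denticle belts than expected were found.

    Attributes
    ----------
    found : int
        Number of candidate belts actually detected.
    expected : int
        Number of belts requested.
    """

    def __init__(self, message, found, expected):
        super().__init__(message)
        self.found = found
        self.expected = expected


class AmbiguityError(SegmorphError):
    """Detected bands overlap and cannot be assigned unique borders."""


class RenderResolutionError(SegmorphError):
    """Requested raster resolution cannot resolve a denticle belt (< 1 px)."""


class InvalidAnnotationError(SegmorphError, ValueError):
    """A belt annotation violates its ordering invariant."""


class DataError(SegmorphError):
    """An input table is malformed or inconsistent."""
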