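"""Exception hierarchy for the ioct-hrfuse pipeline.

Every stage raises a subclass of :class:`IoctHrfuseError` so the pipeline
driver can record per-interval failures and continue.
"""


class IoctHrfuseError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(IoctHrfuseError, ValueError):
    """A phantom or scene specification violates its invariants."""


class InvalidScriptError(IoctHrfuseError, ValueError):
    """A scene script is empty or internally inconsistent."""


class InvalidInputError(IoctHrfuseError, ValueError):
    """An operation received input outside its contract."""


class NoScanRegionError(IoctHrfuseError):
    """No near-rectangular bright quadrilateral found in a microscope frame."""


class ArrowNotFoundError(IoctHrfuseError):
    """A coloured arrow glyph is absent inside the scan rectangle."""

    def __init__(self, colour: str):
        self.colour = colour
        super().__init__(f"no {colour} arrow pixels inside the scan rectangle")


class DegenerateImageError(IoctHrfuseError):
    """An image is constant and cannot be registered."""


class SegmentationFailedError(IoctHrfuseError):
    """The heuristic layer segmenter found no retinal signal."""


class PlacementFailedError(IoctHrfuseError):
    """A region of interest could not be placed inside its target label."""

    def __init__(self, roi_name: str, detail: str = ""):
        self.roi_name = roi_name
        msg = f"no valid placement for ROI '{roi_name}'"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class DegenerateBackgroundError(IoctHrfuseError):
    """Background ROI has zero variance; SNR is undefined."""


class DegenerateRegionError(IoctHrfuseError):
    """A metric ROI is constant where variance is required."""


class InvalidMetricError(IoctHrfuseError, ValueError):
    """A quality metric value is NaN or otherwise unusable."""


class InsufficientCorpusError(IoctHrfuseError, ValueError):
    """Too few images to fit a natural-scene-statistics model."""


class ShapeMismatchError(IoctHrfuseError, ValueError):
    """Two images that must share a shape do not."""
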