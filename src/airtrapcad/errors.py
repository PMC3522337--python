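"""Exception hierarchy for the air-trapping CAD pipeline.

Every stage raises a subclass of :class:`AirTrapError` so callers (and the
pipeline runner) can catch failures per subject and keep going.
"""


class AirTrapError(Exception):
    """Base class for all pipeline errors."""


class InputError(AirTrapError):
    """Unreadable or malformed input (paths, manifests, label lists)."""


class FormatError(InputError):
    """On-disk data violates the expected format (e.g. mixed DICOM series)."""


class MetadataError(InputError):
    """Required acquisition metadata is missing; message names the field."""


class ParameterError(AirTrapError):
    """A tunable parameter is outside its valid range."""


class DegenerateInputError(AirTrapError):
    """Input is valid in form but degenerate (e.g. zero inspiration area)."""


class SegmentationError(AirTrapError):
    """Lung segmentation found no lung component in any slice."""


class ContourCollapseError(SegmentationError):
    """An active contour collapsed below the minimum size during evolution."""


class AirwayTrackingError(AirTrapError):
    """No plausible tracheal air column could be seeded or followed."""


class CarinaNotFoundError(AirwayTrackingError):
    """The tracked airway never bifurcates."""


class FitError(AirTrapError):
    """A statistical model could not be fitted (too few samples, zero variance)."""
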