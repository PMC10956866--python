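"""Exception hierarchy shared across the toolkit."""


class FacsortError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FacsortError):
    """A file could not be parsed (FCS segment, CSV cell, gate file)."""


class ValidationError(FacsortError):
    """An input value violates a documented invariant."""


class InsufficientEventsError(ValidationError):
    """Too few events for a reliable density estimate or gate fit."""


class DegenerateDataError(ValidationError):
    """Events collapse onto a point or line on a gating axis."""


class NoContourError(FacsortError):
    """Contour extraction produced no usable closed polygon."""


class GeometryError(FacsortError):
    """Contour/gate geometry is inconsistent (e.g. disjoint extents)."""


class TransformMismatchError(ValidationError):
    """Gate and event table are not in the same transform space."""


class WorklistError(ValidationError):
    """Base for worklist validation failures."""


class CapacityError(WorklistError):
    """Tube position outside the housing capacity."""


class WellError(WorklistError):
    """Destination well label is not a valid 96-well position."""


class DuplicateEntryError(WorklistError):
    """Duplicate sample name or tube position in a worklist."""
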