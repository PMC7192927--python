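"""Exception hierarchy shared across the package."""


class DropPackError(Exception):
    """Base class for all droppack errors."""


class GeometryError(DropPackError, ValueError):
    """Invalid or non-physical droplet geometry (e.g. arccos argument out of range)."""


class SingularFitError(DropPackError, ValueError):
    """Rank-deficient regression design; the message names the deficient direction."""


class TriangulationError(DropPackError, ValueError):
    """Fewer than three points, or all points collinear."""


class ImageSizeError(DropPackError, ValueError):
    """Requested image frame too small to contain the rendered objects."""


class CapacityError(DropPackError, RuntimeError):
    """No vacant lattice sites left to place additional droplets."""


class LayoutError(DropPackError, ValueError):
    """Hexagonal bin layout is inconsistent (overlapping bins / bad spacing)."""


class InsufficientDataError(DropPackError, ValueError):
    """Not enough observations for the requested statistic."""


class DetectionError(DropPackError, ValueError):
    """Pair-image measurement did not find exactly two droplets."""


class StageError(DropPackError, RuntimeError):
    """A pipeline stage failed; carries the stage name and input identifier."""

    def __init__(self, stage: str, message: str, input_id: str | None = None):
        self.stage = stage
        self.input_id = input_id
        tag = f" [{input_id}]" if input_id else ""
        super().__init__(f"stage '{stage}'{tag}: {message}")


class NonPhysicalAngleWarning(UserWarning):
    """A predicted contact angle fell outside the physical DIB range [0°, 90°]."""
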