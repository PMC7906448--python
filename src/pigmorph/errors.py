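"""Exception hierarchy for the measurement pipeline."""


class PigmorphError(Exception):
    """Base class for pipeline errors."""


class NoObjectError(PigmorphError):
    """Segmentation found no foreground component."""


class NoValidFramesError(PigmorphError):
    """Every frame of a video failed quality control."""


class InvalidDepthError(PigmorphError):
    """Depth lookup produced no usable value (all-invalid pixels or
    a non-positive height)."""


class DegenerateContourError(PigmorphError):
    """Contour has fewer than three non-collinear points, so no
    rotated bounding box exists."""


class ConfigError(PigmorphError):
    """Configuration file failed validation."""
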