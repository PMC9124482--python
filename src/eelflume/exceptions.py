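"""Exception hierarchy for the eelflume pipeline."""


class EelflumeError(Exception):
    """Base class for all eelflume errors."""


class CalibrationError(EelflumeError):
    """DLT calibration failed (too few points, degenerate geometry)."""


class ProjectionError(EelflumeError):
    """3D point projects through (or behind) the camera's focal plane."""


class ReconstructionError(EelflumeError):
    """Triangulation is impossible (fewer than two usable views)."""


class SchemaError(EelflumeError):
    """An input file does not match the expected column schema."""
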