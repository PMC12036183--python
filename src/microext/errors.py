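"""Exception types shared across the toolkit."""


class MicroextError(Exception):
    """Base class for all toolkit errors."""


class InvalidGeometryError(MicroextError, ValueError):
    """Specimen geometry with non-positive or missing dimensions."""


class InvalidParamsError(MicroextError, ValueError):
    """Mechanical parameter set violating its invariants."""


class InvalidSpecError(MicroextError, ValueError):
    """Hardware spec (actuator, load cell, camera) violating its invariants."""


class TravelLimitError(MicroextError, ValueError):
    """Commanded actuator motion would exceed the travel limit."""


class SaturationError(MicroextError, RuntimeError):
    """Load-cell reading clipped at capacity where a clean signal is required."""


class CalibrationError(MicroextError, RuntimeError):
    """Calibration workflow cannot proceed (bad signal, missing weight, ...)."""


class ConfigError(MicroextError, ValueError):
    """Experiment or analysis configuration violating its invariants."""


class TrackingError(MicroextError, RuntimeError):
    """Landmark tracking failure."""


class PartialTrackError(TrackingError):
    """A landmark was lost (count changed) at a named frame."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"landmark count changed at frame {frame_index}")


class AmbiguousMatchError(TrackingError):
    """Frame-to-frame landmark assignment is not unique within the gate."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(
            message or f"ambiguous landmark assignment at frame {frame_index}"
        )


class SchemaError(MicroextError, ValueError):
    """A log file does not conform to the declared CSV schema."""
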