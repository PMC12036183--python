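"""Load-cell calibration: reference-weight force, offset zeroing, gain fit.

The workflow mirrors bench practice with a strain-gauge cell: hang nothing and
average readings to set the offset ("zero" the sensor), hang a weighed
reference object and solve for the gain that maps (reading - offset) to the
known force, then sanity-check the gain against a previous calibration — a
large change suggests a damaged cell.  Re-orienting the cell (vertical
calibration pose to horizontal working pose) shifts the offset by the arm's
own weight, so the workflow re-zeroes after mounting.

Single-point gain calibration is the default, matching the workflow this
toolkit emulates; :func:`calibrate_gain_multipoint` offers a least-squares
alternative over several weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, SaturationError
from .instrument import VirtualLoadCell

__all__ = [
    "STANDARD_GRAVITY_M_PER_S2",
    "CalibrationResult",
    "CalibratedForceSensor",
    "weight_to_force",
    "set_offset",
    "calibrate_gain",
    "calibrate_gain_multipoint",
    "validate_calibration",
]

#: Default gravitational acceleration.  Conventions in the field vary between
#: 9.81 and 9.806 m/s^2; the constant is an explicit argument everywhere.
STANDARD_GRAVITY_M_PER_S2 = 9.80665


def weight_to_force(mass_g: float,
                    g_m_per_s2: float = STANDARD_GRAVITY_M_PER_S2) -> float:
    """F = m g for a reference weight, returned in uN.

    ``mass_g`` is in grams; 1 g under g = 9.81 m/s^2 gives 9810 uN (9.81 mN).
    """
    if mass_g < 0:
        raise CalibrationError("mass must be >= 0")
    return mass_g * g_m_per_s2 * 1e3  # g * (m/s^2) -> uN


@dataclass(frozen=True)
class CalibrationResult:
    """Offset/gain pair mapping bridge units to force, with provenance."""

    offset_units: float
    gain_uN_per_unit: float
    reference_force_uN: float
    n_samples: int
    residual_sd_units: float
    timestamp: str = ""

    def __post_init__(self):
        if not (self.gain_uN_per_unit > 0):
            raise CalibrationError("gain must be > 0")
        if self.residual_sd_units < 0:
            raise CalibrationError("residual sd must be >= 0")


def set_offset(cell: VirtualLoadCell, n_samples: int = 100,
               rng: np.random.Generator | None = None) -> float:
    """Average ``n_samples`` unloaded readings to establish the zero.

    Contract (cannot be verified in software): nothing is on the cell.
    Saturated readings abort the calibration.
    """
    if n_samples < 1:
        raise CalibrationError("n_samples must be >= 1")
    reading = cell.read_bridge(n_samples=n_samples, rng=rng)
    if reading.saturated:
        raise SaturationError("sensor saturated while setting offset")
    return reading.mean_units


def calibrate_gain(cell: VirtualLoadCell, target_force_uN: float,
                   offset_units: float, n_samples: int = 100,
                   rng: np.random.Generator | None = None,
                   timestamp: str = "") -> CalibrationResult:
    """Single-point gain: target force over the offset-corrected mean reading.

    Pre-condition: the offset has been set and the reference weight producing
    ``target_force_uN`` is loaded on the cell.  A mean reading at or below the
    offset means the weight is missing or the cell is damaged.
    """
    if not (target_force_uN > 0):
        raise CalibrationError("target force must be > 0")
    if n_samples < 1:
        raise CalibrationError("n_samples must be >= 1")
    reading = cell.read_bridge(n_samples=n_samples, rng=rng)
    if reading.saturated:
        raise SaturationError("sensor saturated during gain calibration")
    signal = reading.mean_units - offset_units
    if signal <= 0:
        raise CalibrationError(
            "non-positive signal: is the reference weight on the cell?"
        )
    return CalibrationResult(
        offset_units=offset_units,
        gain_uN_per_unit=target_force_uN / signal,
        reference_force_uN=target_force_uN,
        n_samples=n_samples,
        residual_sd_units=reading.sd_units,
        timestamp=timestamp,
    )


def calibrate_gain_multipoint(readings_units, forces_uN) -> CalibrationResult:
    """Least-squares gain/offset over several (reading, force) pairs.

    Off by default in the workflow; provided for users who prefer a
    regression over the single-point estimate.
    """
    readings = np.asarray(readings_units, dtype=float)
    forces = np.asarray(forces_uN, dtype=float)
    if readings.size < 2 or readings.size != forces.size:
        raise CalibrationError("need >= 2 matched (reading, force) pairs")
    slope, intercept = np.polyfit(readings, forces, 1)
    if slope <= 0:
        raise CalibrationError("non-positive fitted gain")
    resid = forces - (slope * readings + intercept)
    return CalibrationResult(
        offset_units=-intercept / slope,
        gain_uN_per_unit=float(slope),
        reference_force_uN=float(forces.max()),
        n_samples=int(readings.size),
        residual_sd_units=float(np.std(resid / slope, ddof=1)),
    )


def validate_calibration(previous: CalibrationResult, current: CalibrationResult,
                         tolerance_frac: float = 0.1) -> str:
    """'pass' when the gain change is within tolerance, else 'warn'.

    A large gain change between calibrations of the same cell suggests the
    sensor was damaged in between.
    """
    change = abs(current.gain_uN_per_unit - previous.gain_uN_per_unit)
    return "warn" if change / previous.gain_uN_per_unit > tolerance_frac else "pass"


class CalibratedForceSensor:
    """A load cell plus its calibration: converts bridge units to uN."""

    def __init__(self, cell: VirtualLoadCell, calibration: CalibrationResult):
        self.cell = cell
        self.calibration = calibration

    def rezero(self, n_samples: int = 100,
               rng: np.random.Generator | None = None) -> None:
        """Re-run offset zeroing (e.g. after re-orienting the cell)."""
        offset = set_offset(self.cell, n_samples=n_samples, rng=rng)
        self.calibration = CalibrationResult(
            offset_units=offset,
            gain_uN_per_unit=self.calibration.gain_uN_per_unit,
            reference_force_uN=self.calibration.reference_force_uN,
            n_samples=n_samples,
            residual_sd_units=self.calibration.residual_sd_units,
            timestamp=self.calibration.timestamp,
        )

    def measure_force(self, n_samples: int = 1,
                      rng: np.random.Generator | None = None):
        """(force_uN, saturated): offset-corrected, gain-scaled mean reading."""
        reading = self.cell.read_bridge(n_samples=n_samples, rng=rng)
        force = ((reading.mean_units - self.calibration.offset_units)
                 * self.calibration.gain_uN_per_unit)
        return force, reading.saturated
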