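"""Hardware abstraction for the micro-extensometer, with simulated back-ends.

Three device roles are defined: a screw-drive stepper actuator, a strain-gauge
load cell read through an amplified Wheatstone bridge, and a camera producing
grayscale snapshots.  The simulated implementations are wired to the specimen
model and define the unit conventions of the whole toolkit:

* actuator position is held internally as an integer step count and exposed in
  nanometres; it is therefore always an exact integer multiple of the step
  size and converting out and back is lossless;
* the bridge reading is ``force / true_gain + true_offset + noise`` in
  dimensionless amplifier units, so calibration code can recover offset and
  gain without ever seeing the hidden truth;
* frames are 8-bit grayscale, dark landmarks on a bright background (India-ink
  dots on a pale specimen), with a known pixel scale.

Real-hardware back-ends would implement the same three surfaces (``move``,
``read``, ``capture``); nothing downstream of this module knows whether the
device is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError, TravelLimitError
from .specimen import (
    SpecimenGeometry,
    SpecimenState,
    grip_separation_um,
    landmark_positions,
)

__all__ = [
    "ActuatorSpec",
    "LoadCellSpec",
    "CameraConfig",
    "Frame",
    "BridgeReading",
    "VirtualActuator",
    "VirtualLoadCell",
    "step_size_um",
    "render_frame",
]


@dataclass(frozen=True)
class ActuatorSpec:
    """Screw-drive stepper actuator.

    Defaults describe a 1-mm-pitch screw on a 200-step (1.8 deg) motor:
    5 um of travel per full step.  ``microstep_divisor`` subdivides full steps.
    An optional ``backlash_um`` exists for robustness experiments; it is zero
    by default (the drive has no noticeable looseness).
    """

    pitch_um_per_rev: float = 1000.0
    full_steps_per_rev: int = 200
    microstep_divisor: int = 1
    travel_limit_um: float = 50_000.0
    backlash_um: float = 0.0

    def __post_init__(self):
        if not (self.pitch_um_per_rev > 0):
            raise InvalidSpecError("pitch must be > 0")
        if self.full_steps_per_rev <= 0 or self.microstep_divisor <= 0:
            raise InvalidSpecError("steps per rev and microstep divisor must be > 0")
        if not (self.travel_limit_um > 0):
            raise InvalidSpecError("travel limit must be > 0")


def step_size_um(spec: ActuatorSpec) -> float:
    """Linear travel per (micro)step: pitch / (full steps x microstep divisor)."""
    return spec.pitch_um_per_rev / (spec.full_steps_per_rev * spec.microstep_divisor)


class VirtualActuator:
    """Position bookkeeping for the simulated screw drive.

    Position is an integer number of steps from the home position; the
    nanometre value is derived, never stored, so there is no drift.
    """

    def __init__(self, spec: ActuatorSpec | None = None):
        self.spec = spec or ActuatorSpec()
        self.position_steps: int = 0

    @property
    def step_size_um(self) -> float:
        return step_size_um(self.spec)

    @property
    def position_um(self) -> float:
        return self.position_steps * self.step_size_um

    @property
    def position_nm(self) -> float:
        return self.position_steps * self.step_size_um * 1e3

    def move_steps(self, n_steps: int) -> float:
        """Move by ``n_steps`` (signed); returns the new position in nm.

        Raises :class:`TravelLimitError` (without moving) if the target lies
        outside ``[0, travel_limit_um]``.
        """
        n_steps = int(n_steps)
        target = self.position_steps + n_steps
        target_um = target * self.step_size_um
        if target_um < 0 or target_um > self.spec.travel_limit_um:
            raise TravelLimitError(
                f"target {target_um:.3f} um outside [0, {self.spec.travel_limit_um}] um"
            )
        self.position_steps = target
        return self.position_nm


@dataclass(frozen=True)
class LoadCellSpec:
    """Hidden truth of the simulated load cell.

    ``true_gain_uN_per_unit`` and ``true_offset_units`` are what calibration
    must recover; downstream code should only ever use calibrated values.  The
    default noise (0.01 units at 1000 uN/unit gain) gives an RMS force noise
    of about 10 uN, matching the resolution of the 10 g parallel-beam cells
    used with this class of instrument.  ``capacity_uN`` defaults to 10 g.
    """

    true_gain_uN_per_unit: float = 1000.0
    true_offset_units: float = 0.15
    noise_sd_units: float = 0.01
    capacity_uN: float = 98_066.5

    def __post_init__(self):
        if not (self.true_gain_uN_per_unit > 0):
            raise InvalidSpecError("gain must be > 0")
        if self.noise_sd_units < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if not (self.capacity_uN > 0):
            raise InvalidSpecError("capacity must be > 0")


@dataclass(frozen=True)
class BridgeReading:
    mean_units: float
    n_samples: int
    saturated: bool
    sd_units: float = 0.0


class VirtualLoadCell:
    """Simulated bridge-amplified load cell.

    The applied force is set by whoever owns the physics (the bench wires it
    to the specimen; calibration scripts hang a known weight on it).  An
    orientation-dependent ``mount_offset_units`` models the shift observed
    when the cell is turned from the vertical calibration pose to the
    horizontal working pose (the arm's own weight), which the documented
    re-zeroing step must cancel.
    """

    def __init__(self, spec: LoadCellSpec | None = None,
                 rng: np.random.Generator | None = None):
        self.spec = spec or LoadCellSpec()
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.applied_force_uN: float = 0.0
        self.mount_offset_units: float = 0.0

    def set_orientation(self, orientation: str,
                        shift_units: float = 0.05) -> None:
        """'vertical' (calibration pose) or 'horizontal' (working pose)."""
        if orientation not in ("vertical", "horizontal"):
            raise InvalidSpecError(f"unknown orientation {orientation!r}")
        self.mount_offset_units = 0.0 if orientation == "vertical" else shift_units

    def sample_units(self, n_samples: int = 1,
                     rng: np.random.Generator | None = None):
        """Raw per-sample readings (units) and a saturation flag.

        Saturation clamps the noiseless signal at +/- capacity and sets a
        flag rather than raising (real amplifiers clip).
        """
        n_samples = int(n_samples)
        if n_samples < 1:
            raise InvalidSpecError("n_samples must be >= 1")
        force = self.applied_force_uN
        saturated = abs(force) > self.spec.capacity_uN
        if saturated:
            force = math.copysign(self.spec.capacity_uN, force)
        clean = (force / self.spec.true_gain_uN_per_unit
                 + self.spec.true_offset_units + self.mount_offset_units)
        gen = rng if rng is not None else self.rng
        if self.spec.noise_sd_units > 0:
            samples = clean + gen.normal(0.0, self.spec.noise_sd_units, n_samples)
        else:
            samples = np.full(n_samples, clean)
        return samples, saturated

    def read_bridge(self, n_samples: int = 1,
                    rng: np.random.Generator | None = None) -> BridgeReading:
        """Mean of ``n_samples`` bridge readings in amplifier units."""
        samples, saturated = self.sample_units(n_samples=n_samples, rng=rng)
        return BridgeReading(
            mean_units=float(samples.mean()),
            n_samples=n_samples,
            saturated=saturated,
            sd_units=float(samples.std(ddof=1)) if n_samples > 1 else 0.0,
        )


@dataclass(frozen=True)
class CameraConfig:
    """Synthetic camera looking along the specimen axis.

    ``x0_um`` is the lab coordinate of the left edge of the field of view;
    the specimen axis runs horizontally through the vertical centre of the
    frame.  Intensities are 8-bit, dark features on a bright background.
    """

    width_px: int = 1200
    height_px: int = 120
    scale_um_per_px: float = 5.0
    x0_um: float = -400.0
    bg_level: float = 235.0
    body_level: float = 210.0
    tag_level: float = 60.0
    dot_level: float = 25.0
    tag_width_um: float = 400.0
    body_halfheight_um: float = 120.0
    dot_radius_um: float = 30.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidSpecError("frame dimensions must be > 0")
        if not (self.scale_um_per_px > 0):
            raise InvalidSpecError("pixel scale must be > 0")


@dataclass
class Frame:
    """One grayscale snapshot with its acquisition metadata."""

    pixels: np.ndarray  # uint8, (height, width)
    scale_um_per_px: float
    timestamp_us: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]


def _column_coverage(x_left_edges: np.ndarray, px_um: float,
                     x1: float, x2: float) -> np.ndarray:
    """Fraction of each pixel column covered by the interval [x1, x2] (um)."""
    lo = np.maximum(x_left_edges, x1)
    hi = np.minimum(x_left_edges + px_um, x2)
    return np.clip((hi - lo) / px_um, 0.0, 1.0)


def render_frame(state: SpecimenState, geom: SpecimenGeometry,
                 landmark_fracs, cam: CameraConfig,
                 rng: np.random.Generator | None = None,
                 timestamp_us: int = 0) -> Frame:
    """Render the mounted specimen: two dark tags, bright body, dark dots.

    Tag separation tracks the grip displacement while the anti-aliased
    circular landmarks sit at :func:`landmark_positions`, so the rendered
    scene reproduces the slip/strain dichotomy the optical pathway exists to
    resolve.  Landmarks outside the field of view are recorded as warnings in
    the frame metadata, not errors.  Deterministic given ``rng``.
    """
    px = cam.scale_um_per_px
    w, h = cam.width_px, cam.height_px
    img = np.full((h, w), cam.bg_level, dtype=float)

    x_edges = cam.x0_um + np.arange(w) * px
    y_c = (h - 1) / 2.0  # specimen axis row (px)

    # Specimen body between the inner tag edges, a band about the axis.
    body_half_px = cam.body_halfheight_um / px
    rows = np.arange(h)
    row_cov = np.clip(body_half_px + 0.5 - np.abs(rows - y_c), 0.0, 1.0)
    sep = grip_separation_um(state, geom) - geom.gauge_length_um  # = x_grip
    body_cov = _column_coverage(x_edges, px, 0.0, geom.gauge_length_um + sep)
    cov2d = row_cov[:, None] * body_cov[None, :]
    img = img * (1 - cov2d) + cam.body_level * cov2d

    # Grip tags: full-height dark rectangles.  The sensor-side tag is fixed
    # at the origin; the actuator-side tag carries the full grip displacement.
    right_inner = geom.gauge_length_um + state.x_grip_um
    for x1, x2 in ((-cam.tag_width_um, 0.0), (right_inner, right_inner + cam.tag_width_um)):
        cov = _column_coverage(x_edges, px, x1, x2)[None, :]
        img = img * (1 - cov) + cam.tag_level * cov

    # Landmark dots: anti-aliased disks on the axis.
    warnings: list[str] = []
    r_px = cam.dot_radius_um / px
    xs_um = landmark_positions(state, geom, landmark_fracs)
    for i, x_um in enumerate(xs_um):
        cx = (x_um - cam.x0_um) / px - 0.5  # centre in pixel coordinates
        if cx < -r_px or cx > w - 1 + r_px:
            warnings.append(f"landmark {i} at {x_um:.1f} um outside field of view")
            continue
        lo_x = max(0, int(math.floor(cx - r_px - 2)))
        hi_x = min(w, int(math.ceil(cx + r_px + 3)))
        lo_y = max(0, int(math.floor(y_c - r_px - 2)))
        hi_y = min(h, int(math.ceil(y_c + r_px + 3)))
        yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        dist = np.hypot(xx - cx, yy - y_c)
        cov = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        sub = img[lo_y:hi_y, lo_x:hi_x]
        img[lo_y:hi_y, lo_x:hi_x] = sub * (1 - cov) + cam.dot_level * cov

    if cam.noise_sd > 0:
        gen = rng if rng is not None else np.random.default_rng(0)
        img = img + gen.normal(0.0, cam.noise_sd, img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Frame(pixels=pixels, scale_um_per_px=px,
                 timestamp_us=int(timestamp_us), warnings=warnings)
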