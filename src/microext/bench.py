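"""The virtual test bench: specimen physics wired to the simulated devices.

A :class:`VirtualBench` owns one specimen (geometry, constitutive parameters,
evolving state), one actuator, one load cell and optionally one camera, plus a
simulated clock in microseconds.  All randomness derives from a single seed
through a :class:`numpy.random.SeedSequence`, so an experiment is reproducible
from its configuration alone.

The bench is the only place where the hidden truth (specimen force, true
sensor gain) meets the device surfaces; controller and analysis code see only
what a real instrument would provide — calibrated readings, step counts,
frames.
"""

from __future__ import annotations

import math

import numpy as np

from .calibration import CalibratedForceSensor
from .instrument import (
    ActuatorSpec,
    CameraConfig,
    Frame,
    LoadCellSpec,
    VirtualActuator,
    VirtualLoadCell,
    render_frame,
)
from .specimen import (
    MechanicalParams,
    SpecimenGeometry,
    SpecimenState,
    evolve,
    landmark_positions,
    specimen_force,
)

__all__ = ["VirtualBench"]


class VirtualBench:
    """Simulated micro-extensometer with a mounted specimen."""

    #: Bridge sampling rate used to time-stamp raw readings (Hz).
    sample_rate_hz = 100.0

    def __init__(self, geometry: SpecimenGeometry, params: MechanicalParams,
                 actuator_spec: ActuatorSpec | None = None,
                 cell_spec: LoadCellSpec | None = None,
                 camera: CameraConfig | None = None,
                 landmark_fracs=(0.2, 0.8),
                 seed: int = 0):
        self.geometry = geometry
        self.params = params
        self.state = SpecimenState()
        self.actuator = VirtualActuator(actuator_spec)
        ss = np.random.SeedSequence(seed)
        cell_rng, cam_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        self.cell = VirtualLoadCell(cell_spec, rng=cell_rng)
        self.camera = camera
        self._cam_rng = cam_rng
        self.landmark_fracs = tuple(landmark_fracs)
        self.clock_us: int = 0
        self.raw_stream: list[tuple[int, float, float]] = []

    # -- physics/clock ----------------------------------------------------

    @property
    def grip_um(self) -> float:
        """Grip displacement imposed on the specimen (actuator position)."""
        return self.actuator.position_um

    def advance(self, dt_s: float) -> None:
        """Let time pass with the grip held at the current actuator position."""
        self.state = evolve(self.state, self.geometry, self.params,
                            self.grip_um, dt_s)
        self.clock_us += int(round(dt_s * 1e6))

    def move_steps(self, n_steps: int, motion_time_s: float = 1e-3) -> float:
        """Move the actuator and apply the new grip position to the specimen.

        The screw travels fast relative to material time scales, so the move
        is modelled as a step change followed by a token ``motion_time_s``.
        """
        pos_nm = self.actuator.move_steps(n_steps)
        self.advance(motion_time_s)
        return pos_nm

    def true_force_uN(self) -> float:
        """Ground-truth transmitted force (hidden from controller code)."""
        return specimen_force(self.state, self.geometry, self.params)

    def landmark_positions_um(self) -> np.ndarray:
        return landmark_positions(self.state, self.geometry, self.landmark_fracs)

    # -- acquisition ------------------------------------------------------

    def acquire_force(self, sensor: CalibratedForceSensor, n_samples: int = 10):
        """Average ``n_samples`` bridge samples through the calibrated sensor.

        The acquisition occupies ``n_samples / sample_rate_hz`` of simulated
        time; each raw sample is appended to the MRX-style raw stream with its
        own timestamp.  Returns ``(force_uN, saturated)``.
        """
        n_samples = int(n_samples)
        dt = n_samples / self.sample_rate_hz
        self.advance(dt)
        self.cell.applied_force_uN = self.true_force_uN()
        samples, saturated = self.cell.sample_units(n_samples=n_samples)
        t0 = self.clock_us - int(round(dt * 1e6))
        step_us = int(round(1e6 / self.sample_rate_hz))
        pos_nm = self.actuator.position_nm
        for i, s in enumerate(samples):
            self.raw_stream.append((t0 + (i + 1) * step_us, float(s), pos_nm))
        cal = sensor.calibration
        force = (float(samples.mean()) - cal.offset_units) * cal.gain_uN_per_unit
        return force, saturated

    def snapshot(self) -> Frame:
        if self.camera is None:
            raise RuntimeError("bench has no camera configured")
        return render_frame(self.state, self.geometry, self.landmark_fracs,
                            self.camera, rng=self._cam_rng,
                            timestamp_us=self.clock_us)

    # -- convenience ------------------------------------------------------

    def steps_for_um(self, distance_um: float) -> int:
        """Integer steps realising ``distance_um``; must divide exactly."""
        step = self.actuator.step_size_um
        n = distance_um / step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"{distance_um} um is not an integer multiple of the "
                f"{step} um step size"
            )
        return int(round(n))
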