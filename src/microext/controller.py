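"""Experiment engine: ramp and creep stretching with synchronized logging.

Two experiment modes are provided.

``ramp``
    Stretch by a fixed total distance in equal steps: move one step, wait a
    configured stabilization time, read the force, capture a snapshot, append
    a record.  On normal completion the actuator returns to its starting
    position.  A wait time of -1 enables external-trigger mode: the loop
    blocks on a confirmation callback at each step (for cameras that are not
    software-integrated, e.g. a confocal).

``creep``
    Approach at a constant rate until a force threshold is reached, then hold
    the force there for a fixed duration by issuing steps whenever the
    measured force falls below the threshold minus a deadband (default 1 % of
    the threshold), sampling once per control period.

Each record carries position (nm), calibrated force (uN) and time (us),
matching the column conventions of the per-step experiment log; one snapshot
is captured per record when a camera is configured.  A stop request exits the
loop after the current step with the partial log intact and the actuator left
where it is (the user returns it manually).

Rupture is not acted on during a run — the specimen's collapse to zero force
is simply recorded, and the end status reports it; detection and localisation
of the rupture step is post-hoc analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .bench import VirtualBench
from .calibration import CalibratedForceSensor
from .errors import ConfigError
from .instrument import Frame

__all__ = [
    "ExperimentConfig",
    "StepRecord",
    "ExperimentLog",
    "StopFlag",
    "run_ramp",
    "run_creep",
    "manual_step",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one stretching experiment.

    ``wait_time_s`` is the stabilization wait between a step and its force
    reading; -1 selects external-trigger mode.  ``creep_threshold_uN`` of 0
    disables force holding (plain ramp semantics).  ``approach_rate_um_per_s``
    sets the constant approach rate in creep mode; the default is one step
    per second.
    """

    mode: str = "ramp"
    distance_um: float = 250.0
    step_size_um: float = 5.0
    wait_time_s: float = 1.0
    creep_threshold_uN: float = 0.0
    approach_rate_um_per_s: Optional[float] = None
    creep_deadband_frac: float = 0.01
    control_period_s: float = 1.0
    max_duration_s: float = 600.0
    n_force_samples: int = 10
    settle_time_s: float = 0.05
    snapshots: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("ramp", "creep"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not (self.distance_um > 0 and self.step_size_um > 0):
            raise ConfigError("distance and step size must be > 0")
        if self.wait_time_s < 0 and self.wait_time_s != -1:
            raise ConfigError("wait time must be >= 0, or -1 for external trigger")
        if self.creep_threshold_uN < 0:
            raise ConfigError("creep threshold must be >= 0")
        if not (0 < self.creep_deadband_frac < 1):
            raise ConfigError("deadband fraction must be in (0, 1)")
        if self.n_force_samples < 1:
            raise ConfigError("need at least one force sample per reading")

    @property
    def n_steps(self) -> int:
        return math.ceil(self.distance_um / self.step_size_um)


@dataclass(frozen=True)
class StepRecord:
    step_index: int
    position_nm: float
    force_uN: float
    time_us: int
    snapshot_path: str | None = None


@dataclass
class ExperimentLog:
    config: ExperimentConfig
    records: list[StepRecord] = field(default_factory=list)
    frames: list[Frame] = field(default_factory=list)
    raw_stream: list[tuple[int, float, float]] = field(default_factory=list)
    status: str = "completed"  # completed | ruptured | stopped | timed_out
    start_label: str = "run"


class StopFlag:
    """Cooperative stop request; checked after each completed step."""

    def __init__(self):
        self._set = False

    def set(self) -> None:
        self._set = True

    def __bool__(self) -> bool:
        return self._set


def _snapshot_name(start_label: str, index: int) -> str:
    return f"{start_label}_{index:04d}.png"


def _take_record(bench: VirtualBench, sensor: CalibratedForceSensor,
                 config: ExperimentConfig, log: ExperimentLog,
                 step_index: int, position_nm: float,
                 force: float | None = None, saturated: bool = False):
    """Read force (unless given), optionally snapshot, append one record."""
    if force is None:
        force, saturated = bench.acquire_force(sensor, config.n_force_samples)
    path = None
    if config.snapshots and bench.camera is not None:
        frame = bench.snapshot()
        path = _snapshot_name(log.start_label, step_index)
        log.frames.append(frame)
    rec = StepRecord(step_index=step_index, position_nm=position_nm,
                     force_uN=force, time_us=bench.clock_us,
                     snapshot_path=path)
    log.records.append(rec)
    return rec, saturated


def run_ramp(config: ExperimentConfig, bench: VirtualBench,
             sensor: CalibratedForceSensor,
             stop: Optional[StopFlag] = None,
             confirm: Optional[Callable[[int], None]] = None,
             on_step: Optional[Callable[[StepRecord], None]] = None,
             start_label: str = "run") -> ExperimentLog:
    """Automated constant-step stretching to a total distance.

    The full travel is validated against the actuator limit before the first
    step.  On completion (including rupture) the actuator returns to its
    starting position; after a stop it stays put.
    """
    steps_per_move = bench.steps_for_um(config.step_size_um)
    start_steps = bench.actuator.position_steps
    total_um = bench.actuator.position_um + config.n_steps * config.step_size_um
    if total_um > bench.actuator.spec.travel_limit_um:
        raise ConfigError(
            f"ramp to {total_um:.1f} um exceeds the travel limit "
            f"{bench.actuator.spec.travel_limit_um} um"
        )
    if config.wait_time_s == -1 and confirm is None:
        raise ConfigError("external-trigger mode needs a confirm callback")

    log = ExperimentLog(config=config, raw_stream=bench.raw_stream,
                        start_label=start_label)
    for k in range(1, config.n_steps + 1):
        bench.move_steps(steps_per_move)
        if config.wait_time_s == -1:
            confirm(k)
            bench.advance(config.settle_time_s)
        else:
            bench.advance(max(config.wait_time_s, config.settle_time_s))
        position_nm = k * config.step_size_um * 1e3
        rec, saturated = _take_record(bench, sensor, config, log, k, position_nm)
        if on_step is not None:
            on_step(rec)
        if saturated or (stop is not None and stop):
            log.status = "stopped"
            return log

    log.status = "ruptured" if bench.state.ruptured else "completed"
    bench.actuator.move_steps(start_steps - bench.actuator.position_steps)
    bench.advance(config.settle_time_s)
    return log


def run_creep(config: ExperimentConfig, bench: VirtualBench,
              sensor: CalibratedForceSensor,
              stop: Optional[StopFlag] = None,
              on_step: Optional[Callable[[StepRecord], None]] = None,
              start_label: str = "run") -> ExperimentLog:
    """Constant-force (creep) experiment.

    Phase 1 steps at the configured approach rate until the measured force
    reaches the threshold; phase 2 holds the force for ``max_duration_s``,
    issuing steps whenever the reading drops below threshold minus deadband.
    A threshold of 0 falls back to plain ramp semantics.
    """
    if config.creep_threshold_uN == 0:
        return run_ramp(config, bench, sensor, stop=stop, on_step=on_step,
                        start_label=start_label)
    if config.creep_threshold_uN > bench.cell.spec.capacity_uN:
        raise ConfigError("creep threshold exceeds the sensor capacity")

    threshold = config.creep_threshold_uN
    deadband = config.creep_deadband_frac * threshold
    rate = config.approach_rate_um_per_s or config.step_size_um  # one step/s
    steps_per_move = bench.steps_for_um(config.step_size_um)
    approach_dt = config.step_size_um / rate

    log = ExperimentLog(config=config, raw_stream=bench.raw_stream,
                        start_label=start_label)
    t_start_us = bench.clock_us
    k = 0

    def elapsed_s() -> float:
        return (bench.clock_us - t_start_us) / 1e6

    # Phase 1: constant-rate approach.
    force = 0.0
    while force < threshold:
        if elapsed_s() > config.max_duration_s:
            log.status = "timed_out"
            return log
        bench.move_steps(steps_per_move)
        bench.advance(approach_dt)
        k += 1
        rec, saturated = _take_record(bench, sensor, config, log, k,
                                      bench.actuator.position_nm)
        force = rec.force_uN
        if on_step is not None:
            on_step(rec)
        if saturated or (stop is not None and stop):
            log.status = "stopped"
            return log

    # Phase 2: hold the force for the configured duration.
    hold_start = elapsed_s()
    while elapsed_s() - hold_start < config.max_duration_s:
        bench.advance(config.control_period_s)
        force, saturated = bench.acquire_force(sensor, config.n_force_samples)
        if saturated:
            log.status = "stopped"
            return log
        # When the reading leaves the band, step back up to mid-band so the
        # next relaxation/creep drift starts with margin on both sides.
        if force < threshold - deadband:
            corrections = 0
            while force < threshold - 0.5 * deadband:
                if corrections >= 200:
                    log.status = "stopped"
                    return log
                bench.move_steps(steps_per_move)
                bench.advance(config.settle_time_s)
                force, saturated = bench.acquire_force(
                    sensor, config.n_force_samples)
                corrections += 1
                if saturated:
                    log.status = "stopped"
                    return log
        k += 1
        rec, _ = _take_record(bench, sensor, config, log, k,
                              bench.actuator.position_nm, force=force)
        if on_step is not None:
            on_step(rec)
        if stop is not None and stop:
            log.status = "stopped"
            return log

    log.status = "completed"
    return log


def manual_step(bench: VirtualBench, sensor: CalibratedForceSensor,
                distance_um: float, wait_time_s: float = 1.0,
                n_force_samples: int = 10, snapshot: bool = True,
                step_index: int = 0, start_label: str = "manual") -> StepRecord:
    """One incremental move + stabilization + reading (+ optional snapshot).

    Repeating manual steps with the schedule of a ramp reproduces the ramp's
    log record for record.
    """
    if distance_um != 0:
        bench.move_steps(bench.steps_for_um(distance_um))
    bench.advance(max(wait_time_s, 0.05))
    force, _ = bench.acquire_force(sensor, n_force_samples)
    path = None
    if snapshot and bench.camera is not None:
        bench.snapshot()
        path = _snapshot_name(start_label, step_index)
    return StepRecord(step_index=step_index, position_nm=bench.actuator.position_nm,
                      force_uN=force, time_us=bench.clock_us, snapshot_path=path)
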