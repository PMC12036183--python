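"""End-to-end workflows: calibrate, stretch, track, analyze.

The :func:`demo` function is the one-command smoke test of the whole
toolkit: it calibrates the simulated load cell against a reference weight,
runs a ramp-to-break experiment on a hypocotyl-like specimen with grip slip
enabled, measures strain both from the actuator and from tracked landmark
dots, and reports the mechanical summary.  Everything is deterministic given
the seed; with the same seed the summary is byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .analysis import MechanicalSummary, summarize
from .bench import VirtualBench
from .calibration import (
    CalibratedForceSensor,
    calibrate_gain,
    set_offset,
    weight_to_force,
)
from .controller import ExperimentConfig, run_ramp
from .instrument import VirtualLoadCell
from .io import write_log
from .presets import (
    HUNDRED_GRAM_CELL,
    arabidopsis_hypocotyl,
    camera_for_gauge,
    fine_actuator,
)
from .tracking import strain_series_from_run

__all__ = ["calibrate_cell", "demo"]


def calibrate_cell(cell: VirtualLoadCell, reference_mass_g: float,
                   g_m_per_s2: float | None = None,
                   n_samples: int = 100) -> CalibratedForceSensor:
    """The full bench calibration workflow on a (simulated) load cell.

    Vertical pose: zero the unloaded cell, hang the weighed reference and
    solve for the gain.  Working pose: re-orient horizontally and re-zero
    (the arm's own weight shifts the offset).  Returns the calibrated sensor
    ready for force measurement.
    """
    kwargs = {} if g_m_per_s2 is None else {"g_m_per_s2": g_m_per_s2}
    reference_force = weight_to_force(reference_mass_g, **kwargs)

    cell.set_orientation("vertical")
    cell.applied_force_uN = 0.0
    offset = set_offset(cell, n_samples=n_samples)

    cell.applied_force_uN = reference_force
    result = calibrate_gain(cell, reference_force, offset, n_samples=n_samples)

    cell.applied_force_uN = 0.0
    cell.set_orientation("horizontal")
    sensor = CalibratedForceSensor(cell, result)
    sensor.rezero(n_samples=n_samples)
    return sensor


def demo(seed: int = 0, out_dir: str | Path | None = None):
    """Calibrate, stretch to rupture, track, analyze — in one call.

    Returns ``(log, summary_dict)``.  When ``out_dir`` is given, the run
    directory and a ``summary.json`` are written there.
    """
    geom, params = arabidopsis_hypocotyl(with_slip=True)
    bench = VirtualBench(
        geometry=geom, params=params,
        actuator_spec=fine_actuator(microstep_divisor=4),
        cell_spec=HUNDRED_GRAM_CELL,
        camera=camera_for_gauge(geom.gauge_length_um, travel_um=150.0),
        landmark_fracs=(0.15, 0.85),
        seed=seed,
    )
    sensor = calibrate_cell(bench.cell, reference_mass_g=20.0)

    config = ExperimentConfig(
        mode="ramp", distance_um=120.0, step_size_um=1.25,
        wait_time_s=10.0, n_force_samples=10, seed=seed,
    )
    log = run_ramp(config, bench, sensor, start_label=f"demo-seed{seed}")

    series = strain_series_from_run(log, pair=(0, 1))
    forces = np.array([r.force_uN for r in log.records])
    mech: MechanicalSummary = summarize(
        forces, series.landmark_pct, geom, span_steps=30, series=series,
        run_to_break=True,
    )

    summary = {
        "seed": seed,
        "status": log.status,
        "n_steps": len(log.records),
        "calibrated_gain_uN_per_unit": round(
            sensor.calibration.gain_uN_per_unit, 6),
        "youngs_modulus_MPa": round(mech.youngs_modulus_MPa, 3),
        "true_equilibrium_modulus_MPa": params.E_inf_MPa,
        "linear_region_steps": list(mech.linear_region),
        "ultimate_stress_MPa": None if mech.ultimate_stress_MPa is None
        else round(mech.ultimate_stress_MPa, 4),
        "true_ultimate_stress_MPa": params.sigma_ult_MPa,
        "rupture_step": mech.rupture_step,
        "final_landmark_strain_pct": round(float(series.landmark_pct[-1]), 3),
        "final_grip_strain_pct": round(float(series.grip_pct[-1]), 3),
        "slip_verdict": mech.slip_verdict,
    }

    if out_dir is not None:
        root = write_log(log, out_dir)
        (root / "summary.json").write_text(
            json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return log, summary
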