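import numpy as np
import pytest

from microext import (
    ActuatorSpec,
    CameraConfig,
    LoadCellSpec,
    MechanicalParams,
    SpecimenGeometry,
    VirtualBench,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cyl_geom():
    """Hypocotyl-like cylinder: r = 100 um, L0 = 5 mm."""
    return SpecimenGeometry.cylindrical(radius_um=100.0, gauge_length_um=5000.0)


@pytest.fixture
def elastic_params():
    """Pure standard-linear-solid: no yield, no slip, no rupture in range."""
    return MechanicalParams(E_inf_MPa=300.0, E_1_MPa=150.0, tau_s=5.0)


def make_bench(geom, params, *, noise_sd_units=0.0, microstep_divisor=1,
               camera=None, landmark_fracs=(0.2, 0.8), seed=0,
               capacity_uN=980_665.0):
    """A bench with a quiet (or noisy) cell and optional camera."""
    return VirtualBench(
        geometry=geom,
        params=params,
        actuator_spec=ActuatorSpec(microstep_divisor=microstep_divisor),
        cell_spec=LoadCellSpec(true_gain_uN_per_unit=1000.0,
                               true_offset_units=0.15,
                               noise_sd_units=noise_sd_units,
                               capacity_uN=capacity_uN),
        camera=camera,
        landmark_fracs=landmark_fracs,
        seed=seed,
    )


def quiet_sensor(bench):
    """Perfectly calibrated sensor for a noise-free cell (test shortcut)."""
    from microext import CalibratedForceSensor, CalibrationResult

    spec = bench.cell.spec
    cal = CalibrationResult(
        offset_units=spec.true_offset_units + bench.cell.mount_offset_units,
        gain_uN_per_unit=spec.true_gain_uN_per_unit,
        reference_force_uN=1.0,
        n_samples=1,
        residual_sd_units=0.0,
    )
    return CalibratedForceSensor(bench.cell, cal)
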