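"""Reference specimen scenarios and instrument defaults.

These presets define the simulated study conditions used by the demo, the
examples and the test suite.  They are chosen once, on physical grounds, to
be representative of the tissues this class of instrument is used on:

``arabidopsis_hypocotyl``
    A stiff, slender cylindrical organ (radius 100 um, 5 mm gauge length)
    with a tissue-level modulus of a few hundred MPa, an ultimate stress of a
    few MPa, and tag-slip above a holding force well below rupture — the
    regime where actuator-based strain badly overestimates tissue strain.

``onion_epidermal_peel``
    A soft prismatic peel (50 um x 4 mm section) with a modulus around
    10 MPa, yielding near 1 MPa and rupturing near 2 MPa.

``creep_test_specimen``
    A soft specimen with a low yield stress and gentle Lockhart
    extensibility, built for constant-force creep runs at a few mN: plastic
    flow is slow enough for a stepper-quantised controller to hold the force
    within a 1 % deadband.

Moduli are equilibrium values; the transient branch is set to half the
equilibrium modulus with a retardation time of a few seconds, giving the
between-step relaxation these tissues show.
"""

from __future__ import annotations

from .instrument import ActuatorSpec, CameraConfig, LoadCellSpec
from .specimen import MechanicalParams, SpecimenGeometry

__all__ = [
    "arabidopsis_hypocotyl",
    "onion_epidermal_peel",
    "creep_test_specimen",
    "camera_for_gauge",
    "TEN_GRAM_CELL",
    "HUNDRED_GRAM_CELL",
]

#: 10 g parallel-beam cell: ~10 uN RMS force noise at 1000 uN/unit gain.
TEN_GRAM_CELL = LoadCellSpec(true_gain_uN_per_unit=1000.0, true_offset_units=0.15,
                             noise_sd_units=0.01, capacity_uN=98_066.5)

#: 100 g cell for stiffer tissue, same relative noise.
HUNDRED_GRAM_CELL = LoadCellSpec(true_gain_uN_per_unit=1000.0,
                                 true_offset_units=0.15,
                                 noise_sd_units=0.01, capacity_uN=980_665.0)


def arabidopsis_hypocotyl(with_slip: bool = True):
    """(geometry, params) for an etiolated hypocotyl-like specimen."""
    geom = SpecimenGeometry.cylindrical(radius_um=100.0, gauge_length_um=5000.0)
    params = MechanicalParams(
        E_inf_MPa=300.0,
        E_1_MPa=150.0,
        tau_s=3.0,
        sigma_Y_MPa=2.5,
        phi_per_MPa_s=1e-5,
        sigma_ult_MPa=3.0,
        F_hold_uN=40_000.0 if with_slip else float("inf"),
        slip_rate_um_per_s_per_uN=1e-6 if with_slip else 0.0,
    )
    return geom, params


def onion_epidermal_peel(with_slip: bool = True):
    """(geometry, params) for a soft epidermal-peel-like specimen."""
    geom = SpecimenGeometry.prismatic(thickness_um=50.0, width_um=4000.0,
                                      gauge_length_um=5000.0)
    params = MechanicalParams(
        E_inf_MPa=10.0,
        E_1_MPa=5.0,
        tau_s=5.0,
        sigma_Y_MPa=1.0,
        phi_per_MPa_s=0.05,
        sigma_ult_MPa=2.0,
        F_hold_uN=100_000.0 if with_slip else float("inf"),
        slip_rate_um_per_s_per_uN=1e-6 if with_slip else 0.0,
    )
    return geom, params


def creep_test_specimen(with_slip: bool = False):
    """(geometry, params) tuned for constant-force creep experiments."""
    geom = SpecimenGeometry.prismatic(thickness_um=50.0, width_um=4000.0,
                                      gauge_length_um=5000.0)
    params = MechanicalParams(
        E_inf_MPa=6.0,
        E_1_MPa=4.0,
        tau_s=5.0,
        sigma_Y_MPa=0.015,
        phi_per_MPa_s=1e-3,
        sigma_ult_MPa=1.0,
        F_hold_uN=3000.0 if with_slip else float("inf"),
        slip_rate_um_per_s_per_uN=1e-5 if with_slip else 0.0,
    )
    return geom, params


def camera_for_gauge(gauge_length_um: float, travel_um: float = 500.0,
                     scale_um_per_px: float = 5.0,
                     noise_sd: float = 2.0) -> CameraConfig:
    """A camera whose field of view covers the gauge, tags and planned travel."""
    margin = 500.0
    span_um = gauge_length_um + travel_um + 2 * margin
    return CameraConfig(
        width_px=int(span_um / scale_um_per_px),
        height_px=120,
        scale_um_per_px=scale_um_per_px,
        x0_um=-margin,
        noise_sd=noise_sd,
    )


def fine_actuator(microstep_divisor: int = 4) -> ActuatorSpec:
    """The default 1-mm-pitch, 200-step drive with microstepping enabled."""
    return ActuatorSpec(microstep_divisor=microstep_divisor)
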