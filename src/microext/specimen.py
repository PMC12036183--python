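"""Virtual tensile specimen: elastic, viscoelastic, plastic, slipping, rupturing.

The material model is a standard linear solid (an equilibrium spring ``E_inf``
in parallel with a Maxwell branch ``E_1``–``tau``) extended with

* a Bingham-style plastic element following the Lockhart picture of cell-wall
  creep: irreversible strain accrues at rate ``phi * max(0, sigma - sigma_Y)``,
  i.e. only while tensile stress exceeds the yield threshold;
* Coulomb-threshold grip slip: above a holding force ``F_hold`` the specimen
  slides within its mounting tags at a rate proportional to the excess force,
  so actuator displacement and true tissue extension diverge;
* brittle rupture: once stress reaches ``sigma_ult`` the transmitted force is
  zero for the rest of the trajectory.

Sign conventions: displacement and strain are positive in tension; the mounted
specimen cannot transmit compression through its tags, so force is clamped at
zero.  Units are micrometres, seconds, MPa and microNewtons throughout;
conveniently 1 uN / 1 um^2 = 1 MPa exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import InvalidGeometryError, InvalidParamsError

__all__ = [
    "SpecimenGeometry",
    "MechanicalParams",
    "SpecimenState",
    "cross_section_area",
    "tissue_strain",
    "specimen_stress",
    "specimen_force",
    "evolve",
    "landmark_positions",
    "grip_separation_um",
]


@dataclass(frozen=True)
class SpecimenGeometry:
    """Specimen shape and reference (gauge) length.

    ``shape`` is ``"cylindrical"`` (hypocotyl-, stem- or root-like, described by
    ``radius_um``) or ``"prismatic"`` (peel- or leaf-like, described by
    ``thickness_um`` x ``width_um``).  ``gauge_length_um`` is the grip-to-grip
    reference length L0 over which strain is defined.
    """

    shape: str
    gauge_length_um: float
    radius_um: float | None = None
    thickness_um: float | None = None
    width_um: float | None = None

    def __post_init__(self):
        if self.shape not in ("cylindrical", "prismatic"):
            raise InvalidGeometryError(f"unknown shape {self.shape!r}")
        if not (self.gauge_length_um > 0):
            raise InvalidGeometryError("gauge_length_um must be > 0")
        if self.shape == "cylindrical":
            if self.radius_um is None or not (self.radius_um > 0):
                raise InvalidGeometryError("cylindrical shape needs radius_um > 0")
        else:
            if self.thickness_um is None or not (self.thickness_um > 0):
                raise InvalidGeometryError("prismatic shape needs thickness_um > 0")
            if self.width_um is None or not (self.width_um > 0):
                raise InvalidGeometryError("prismatic shape needs width_um > 0")

    @classmethod
    def cylindrical(cls, radius_um: float, gauge_length_um: float) -> "SpecimenGeometry":
        return cls(shape="cylindrical", radius_um=radius_um,
                   gauge_length_um=gauge_length_um)

    @classmethod
    def prismatic(cls, thickness_um: float, width_um: float,
                  gauge_length_um: float) -> "SpecimenGeometry":
        return cls(shape="prismatic", thickness_um=thickness_um,
                   width_um=width_um, gauge_length_um=gauge_length_um)


def cross_section_area(geom: SpecimenGeometry) -> float:
    """Cross-sectional area in um^2.

    Cylindrical specimens use A = pi r^2; prismatic ones A = thickness x width.
    The area is treated as constant during stretch (no Poisson thinning).
    """
    if geom.shape == "cylindrical":
        return math.pi * geom.radius_um**2
    return geom.thickness_um * geom.width_um


@dataclass(frozen=True)
class MechanicalParams:
    """Constitutive parameters of the virtual specimen.

    E_inf_MPa            equilibrium (long-time) elastic modulus
    E_1_MPa              modulus of the transient Maxwell branch; the
                         instantaneous modulus is E_inf + E_1
    tau_s                retardation time of the transient branch
    sigma_Y_MPa          yield stress below which no plastic flow occurs
    phi_per_MPa_s        Lockhart extensibility: plastic strain rate per unit
                         of stress in excess of sigma_Y
    sigma_ult_MPa        ultimate stress; reaching it ruptures the specimen
    F_hold_uN            grip holding force; above it the specimen slips
    slip_rate_um_per_s_per_uN  slip compliance above F_hold
    """

    E_inf_MPa: float
    E_1_MPa: float
    tau_s: float
    sigma_Y_MPa: float = math.inf
    phi_per_MPa_s: float = 0.0
    sigma_ult_MPa: float = math.inf
    F_hold_uN: float = math.inf
    slip_rate_um_per_s_per_uN: float = 0.0

    def __post_init__(self):
        if not (self.E_inf_MPa > 0 and self.E_1_MPa > 0 and self.tau_s > 0):
            raise InvalidParamsError("moduli and tau must be > 0")
        if not (self.sigma_ult_MPa > 0):
            raise InvalidParamsError("sigma_ult_MPa must be > 0")
        if self.sigma_Y_MPa < 0 or self.phi_per_MPa_s < 0:
            raise InvalidParamsError("sigma_Y and phi must be >= 0")
        # With yield enabled, rupture must come later than yield; an infinite
        # sigma_Y just means the plastic element is switched off.
        if math.isfinite(self.sigma_Y_MPa) and not (
                self.sigma_ult_MPa > self.sigma_Y_MPa):
            raise InvalidParamsError("sigma_ult must exceed sigma_Y")
        if self.F_hold_uN < 0 or self.slip_rate_um_per_s_per_uN < 0:
            raise InvalidParamsError("slip parameters must be >= 0")


@dataclass(frozen=True)
class SpecimenState:
    """Material state advanced by :func:`evolve`.

    ``x_grip_um`` is the imposed grip-separation change, ``x_slip_um`` the
    cumulative slip at the grips (both relative to the mounted, untensioned
    configuration).  ``eps_v`` and ``eps_p`` are the dimensionless viscous- and
    plastic-branch strains.  After rupture the mechanical fields are frozen and
    the transmitted force is identically zero.
    """

    t_s: float = 0.0
    x_grip_um: float = 0.0
    x_slip_um: float = 0.0
    eps_v: float = 0.0
    eps_p: float = 0.0
    ruptured: bool = False
    #: tissue strain at the rupture instant; landmarks hold it afterwards
    eps_frozen: float | None = None


def tissue_strain(state: SpecimenState, geom: SpecimenGeometry) -> float:
    """True tissue strain (fraction): grip displacement minus slip, over L0.

    After rupture the broken halves no longer follow the grips; the strain
    seen by the landmarks stays frozen at its rupture value.
    """
    if state.ruptured and state.eps_frozen is not None:
        return state.eps_frozen
    return (state.x_grip_um - state.x_slip_um) / geom.gauge_length_um


def specimen_stress(state: SpecimenState, geom: SpecimenGeometry,
                    params: MechanicalParams) -> float:
    """Tensile stress in MPa, clamped at zero; zero after rupture."""
    if state.ruptured:
        return 0.0
    eps = tissue_strain(state, geom)
    sigma = (params.E_inf_MPa * (eps - state.eps_p)
             + params.E_1_MPa * (eps - state.eps_p - state.eps_v))
    return max(sigma, 0.0)


def specimen_force(state: SpecimenState, geom: SpecimenGeometry,
                   params: MechanicalParams) -> float:
    """Transmitted tensile force in uN (stress times initial area)."""
    return specimen_stress(state, geom, params) * cross_section_area(geom)


def evolve(state: SpecimenState, geom: SpecimenGeometry, params: MechanicalParams,
           x_grip_target_um: float, dt_s: float) -> SpecimenState:
    """Advance the specimen by ``dt_s`` with the grip held at the target.

    The grip displacement is applied as a step at the start of the interval
    (the screw actuator moves fast relative to the material time scales).  The
    coupled laws are

        d eps_v / dt = (eps - eps_p - eps_v) / tau
        d eps_p / dt = phi * max(0, sigma - sigma_Y)
        d x_slip / dt = slip_rate * max(0, F - F_hold)

    with eps the tissue strain.  Integration subdivides ``dt_s`` so each
    substep is at most ``tau/50``; within a substep the viscous branch is
    updated with its exact exponential solution (plastic strain and slip held
    fixed over the substep) and the slow plastic/slip variables explicitly.
    This is unconditionally stable and deterministic.

    Rupture is brittle and one-way: once sigma >= sigma_ult the state keeps
    its fields (force identically zero) and only time advances.
    """
    if not (dt_s > 0):
        raise InvalidParamsError("dt_s must be > 0")
    if state.ruptured:
        return replace(state, t_s=state.t_s + dt_s, x_grip_um=x_grip_target_um)

    L0 = geom.gauge_length_um
    A = cross_section_area(geom)
    # Substep small against every relaxation rate in play: the viscous
    # branch (1/tau) and the stress-decay rates induced by plastic flow
    # (phi * E_glassy) and grip slip (slip_rate * E_glassy * A / L0).
    E_g = params.E_inf_MPa + params.E_1_MPa
    h_max = params.tau_s / 50.0
    rate_p = params.phi_per_MPa_s * E_g
    if rate_p > 0:
        h_max = min(h_max, 1e-3 / rate_p)
    rate_s = params.slip_rate_um_per_s_per_uN * E_g * A / L0
    if rate_s > 0:
        h_max = min(h_max, 1e-3 / rate_s)
    n_sub = max(1, math.ceil(dt_s / h_max))
    h = dt_s / n_sub
    decay = math.exp(-h / params.tau_s)

    x_grip = float(x_grip_target_um)
    x_slip, eps_v, eps_p = state.x_slip_um, state.eps_v, state.eps_p

    def stress(xs: float, ev: float, ep: float) -> float:
        eps = (x_grip - xs) / L0
        s = (params.E_inf_MPa * (eps - ep)
             + params.E_1_MPa * (eps - ep - ev))
        return max(s, 0.0)

    def rates(s: float) -> tuple[float, float]:
        dp = params.phi_per_MPa_s * max(0.0, s - params.sigma_Y_MPa)
        ds = params.slip_rate_um_per_s_per_uN * max(0.0, s * A - params.F_hold_uN)
        return dp, ds

    for _ in range(n_sub):
        sigma = stress(x_slip, eps_v, eps_p)
        if sigma >= params.sigma_ult_MPa:
            return SpecimenState(
                t_s=state.t_s + dt_s, x_grip_um=x_grip, x_slip_um=x_slip,
                eps_v=eps_v, eps_p=eps_p, ruptured=True,
                eps_frozen=(x_grip - x_slip) / L0,
            )
        # Symmetric split: half plastic/slip, exact viscous relaxation,
        # half plastic/slip with rates re-evaluated at the updated state.
        dp, ds = rates(sigma)
        eps_p += 0.5 * h * dp
        x_slip += 0.5 * h * ds
        target = (x_grip - x_slip) / L0 - eps_p
        eps_v = target + (eps_v - target) * decay
        dp, ds = rates(stress(x_slip, eps_v, eps_p))
        eps_p += 0.5 * h * dp
        x_slip += 0.5 * h * ds

    return SpecimenState(t_s=state.t_s + dt_s, x_grip_um=x_grip, x_slip_um=x_slip,
                         eps_v=eps_v, eps_p=eps_p, ruptured=False)


def landmark_positions(state: SpecimenState, geom: SpecimenGeometry,
                       material_fracs: Sequence[float]) -> np.ndarray:
    """Lab-frame positions (um) of material points at fractions of L0.

    The sensor-side grip edge sits at x = 0.  A material point at fraction f
    of the gauge length maps to ``f * L0 * (1 + eps)`` with eps the *tissue*
    strain, so landmark separations grow exactly with true tissue extension
    and are unaffected by grip slip.  (The actuator-side tag, in contrast,
    moves with the full grip displacement; see :func:`grip_separation_um`.)
    """
    fracs = np.asarray(material_fracs, dtype=float)
    if fracs.size and (fracs.min() < 0.0 or fracs.max() > 1.0):
        raise InvalidGeometryError("material fractions must lie in [0, 1]")
    eps = tissue_strain(state, geom)
    return fracs * geom.gauge_length_um * (1.0 + eps)


def grip_separation_um(state: SpecimenState, geom: SpecimenGeometry) -> float:
    """Distance between the inner tag edges: L0 plus the grip displacement."""
    return geom.gauge_length_um + state.x_grip_um
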