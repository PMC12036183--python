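"""Independent fine-step explicit-Euler integrator for the specimen laws.

Kept deliberately naive and separate from the package: it re-states the
constitutive equations directly and integrates them with a tiny explicit
step, serving as the reference the production integrator is checked against.
"""

import math


def euler_force_trajectory(geom, params, grip_schedule, dt_out_s,
                           n_euler_per_out=2000):
    """Force after each (grip_target, hold) segment, by brute-force Euler.

    ``grip_schedule`` is a sequence of grip targets (um); each is applied as
    a step and held for ``dt_out_s``.  Returns the list of forces (uN) at the
    end of each segment.
    """
    L0 = geom.gauge_length_um
    if geom.shape == "cylindrical":
        area = math.pi * geom.radius_um**2
    else:
        area = geom.thickness_um * geom.width_um

    eps_v = eps_p = x_slip = 0.0
    ruptured = False
    h = dt_out_s / n_euler_per_out
    forces = []
    for x_grip in grip_schedule:
        for _ in range(n_euler_per_out):
            if ruptured:
                break
            eps = (x_grip - x_slip) / L0
            sigma = (params.E_inf_MPa * (eps - eps_p)
                     + params.E_1_MPa * (eps - eps_p - eps_v))
            sigma = max(sigma, 0.0)
            if sigma >= params.sigma_ult_MPa:
                ruptured = True
                break
            force = sigma * area
            eps_v += h * (eps - eps_p - eps_v) / params.tau_s
            eps_p += h * params.phi_per_MPa_s * max(0.0, sigma - params.sigma_Y_MPa)
            x_slip += h * params.slip_rate_um_per_s_per_uN * max(
                0.0, force - params.F_hold_uN)
        if ruptured:
            forces.append(0.0)
            continue
        eps = (x_grip - x_slip) / L0
        sigma = max(0.0, params.E_inf_MPa * (eps - eps_p)
                    + params.E_1_MPa * (eps - eps_p - eps_v))
        forces.append(sigma * area)
    return forces
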