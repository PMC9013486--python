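"""Independent brute-force oracles for the C4 model solvers.

These re-derive the coupled supply/demand equations directly from their
algebraic statement and solve the fixed point by plain bisection, fully
independent of the package's root-finding path.
"""

import numpy as np


def enzyme_demand_direct(A, ci, p, c):
    Cm = max(ci - A / p.gm, 0.0)
    Vp = Cm * p.Vpmax / (Cm + c.Kp)
    Rm = c.rm_ratio * p.Rd
    Cs = max(Cm + (Vp - A - Rm) / c.gbs, 0.0)
    gamma_os = c.gamma_star * c.Os * 1000.0
    return (Cs - gamma_os) * p.Vcmax / (Cs + c.Kc * (1 + c.Os / c.Ko)) - p.Rd


def light_demand_direct(A, ci, Jt, p, c):
    Cm = max(ci - A / p.gm, 0.0)
    Rm = c.rm_ratio * p.Rd
    Cs = max(Cm + (c.x * Jt / c.phi - A - Rm) / c.gbs, 1e-9)
    gamma_os = c.gamma_star * c.Os * 1000.0
    gross = ((1 - gamma_os / Cs) * ((1 - c.x) * Jt / 3.0)
             / (1 + 7 * gamma_os / (3 * Cs)))
    return gross - p.Rd


def jt_direct(I2, Jmax, theta):
    s = I2 + Jmax
    return (s - np.sqrt(s * s - 4 * theta * I2 * Jmax)) / (2 * theta)


def bisect_fixed_point(demand, lo, hi, iters=200):
    """Plain bisection on f(A) = A - demand(A); assumes a bracketing sign change."""
    flo = lo - demand(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = mid - demand(mid)
        if (fm < 0) == (flo < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def enzyme_A_oracle(ci, p, c):
    return bisect_fixed_point(
        lambda a: enzyme_demand_direct(a, ci, p, c),
        -p.Rd - 1.0, min(p.Vcmax, p.Vpmax) + 1.0,
    )


def light_A_oracle(ci, I_inc, p, c):
    I2 = p.PSabs * I_inc
    if I2 == 0:
        return -p.Rd
    Jt = jt_direct(I2, p.Jmax, p.theta)
    return bisect_fixed_point(
        lambda a: light_demand_direct(a, ci, Jt, p, c),
        -p.Rd - 1.0, (1 - c.x) * Jt / 3.0 + 1.0,
    )
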