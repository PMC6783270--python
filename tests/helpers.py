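"""Shared independent oracles for the test suite."""

import numpy as np
from scipy.integrate import solve_ivp


def relax_to_equilibrium(total, kd_dimer, kd_hexamer_uM2, t_end=2e3):
    """Integrate the monomer-dimer-hexamer mass-action scheme to its
    long-time limit: an oracle for the root-finding equilibrium solver.
    Rates are chosen fast so t_end far exceeds the relaxation time."""
    k1, k2 = 10.0, 1e-2
    k1r, k2r = k1 * kd_dimer, k2 * kd_hexamer_uM2

    def rhs(t, y):
        m, d, h = y
        f1 = k1 * m * m - k1r * d
        f2 = k2 * d ** 3 - k2r * h
        return [-2.0 * f1, f1 - 3.0 * f2, f2]

    sol = solve_ivp(rhs, (0.0, t_end), [total, 0.0, 0.0], method="LSODA",
                    rtol=1e-12, atol=1e-14)
    return sol.y[:, -1]
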