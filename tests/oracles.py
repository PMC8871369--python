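"""Independent oracles used by the tests.

The equilibrium solver is cross-checked against relaxation of the explicit
mass-action ODE system in which every protomer microstate is a species —
a route that shares no code with the partition-function solver.
"""

import numpy as np
from scipy.integrate import solve_ivp

KON = 10.0  # arbitrary on-rate; only the ratios (the K's) fix the steady state


def ode_relax_c_free(totals, params, t_end=2e4):
    """Steady-state free C and free cAMP by mass-action ODE relaxation.

    Species: free C, free cAMP, and the six protomer states R[c, a].
    Detailed balance against the protomer weights fixes the off-rates:
    C unbinds from a state with a bound cAMP at KON * K_C * alpha^a, and
    the a-th cAMP unbinds from a C-bound protomer at KON * K_A * alpha^c
    with statistical factors (2 - a) on and (a + 1) off.
    """
    KC, KA, al = params.K_C, params.K_A, params.alpha

    def rhs(_t, y):
        C, A = y[0], y[1]
        R = y[2:].reshape(2, 3)
        dR = np.zeros((2, 3))
        dC = dA = 0.0
        for a in range(3):
            f = KON * C * R[0, a]
            b = KON * KC * al ** a * R[1, a]
            dR[0, a] += b - f
            dR[1, a] += f - b
            dC += b - f
        for c in range(2):
            for a in range(2):
                f = KON * (2 - a) * A * R[c, a]
                b = KON * KA * al ** c * (a + 1) * R[c, a + 1]
                dR[c, a] += b - f
                dR[c, a + 1] += f - b
                dA += b - f
        return np.concatenate(([dC, dA], dR.ravel()))

    y0 = np.zeros(8)
    y0[0], y0[1], y0[2] = totals.C_tot, totals.A_tot, totals.R_tot
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-11, atol=1e-13)
    return float(sol.y[0, -1]), float(sol.y[1, -1])


def pooled_ttest(a, b):
    """Long-hand pooled-variance two-sample t statistic and two-tailed p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return float(t), float(p)
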