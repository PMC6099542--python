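"""Independent numerical oracles used by the test suite only."""

import numpy as np
from scipy.integrate import solve_ivp


def ode_tissue_response(p, aif, t_end, n_eval=1201):
    """Reversible-tissue concentration by direct ODE integration.

    Integrates dC_ND/dt = K1*Ca - (k2+k3)*C_ND + k4*C_S,
               dC_S/dt  = k3*C_ND - k4*C_S
    and returns (t, C_ND + C_S).  Independent of the analytic
    exponential-convolution path it is used to check.
    """

    def rhs(t, y):
        ca = aif.parent(t)
        return [p.K1 * ca - (p.k2 + p.k3) * y[0] + p.k4 * y[1], p.k3 * y[0] - p.k4 * y[1]]

    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(
        rhs, (0.0, t_end), [0.0, 0.0], t_eval=t_eval, method="LSODA", rtol=1e-9, atol=1e-12
    )
    return t_eval, sol.y[0] + sol.y[1]


def welch_by_hand(a, b):
    """Welch statistic and Welch-Satterthwaite df from the textbook formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (b.mean() - a.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def permutation_test_greater(a, b, n_perm=2000, seed=0):
    """Permutation p-value for mean(b) > mean(a)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = np.mean(b) - np.mean(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if np.mean(perm[len(a):]) - np.mean(perm[: len(a)]) >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
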