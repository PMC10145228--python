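"""Independent numerical oracles shared by the test modules."""

import numpy as np
from scipy.integrate import solve_ivp


def ode_concentration(tsfd, dose, interval, n_doses, cl, v, ka):
    """One-compartment oral-dosing concentration by direct ODE integration.

    Integrates the gut/central amount system between bolus administrations
    into the gut; independent of the closed-form superposition code path.
    Returns ng/mL.
    """
    ke = cl / v
    dose_times = [d * interval for d in range(n_doses) if d * interval < tsfd]
    y = np.array([0.0, 0.0])  # gut amount (mg), central amount (mg)
    t_now = 0.0
    for t_dose in dose_times:
        if t_dose > t_now:
            sol = solve_ivp(
                lambda t, y: [-ka * y[0], ka * y[0] - ke * y[1]],
                (t_now, t_dose), y, rtol=1e-10, atol=1e-12,
            )
            y = sol.y[:, -1]
            t_now = t_dose
        y = y + np.array([dose, 0.0])
    sol = solve_ivp(
        lambda t, y: [-ka * y[0], ka * y[0] - ke * y[1]],
        (t_now, tsfd), y, rtol=1e-10, atol=1e-12,
    )
    return sol.y[1, -1] / v * 1000.0
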