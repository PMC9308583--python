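import logging

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import medastac as m

logging.getLogger("medastac").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def schedule():
    return m.parse_frame_schedule(m.DEFAULT_FRAMING)


@pytest.fixture(scope="session")
def inp():
    """Noise-free, correctly calibrated default input function."""
    return m.true_input_function()


@pytest.fixture(scope="session")
def prep(inp, schedule):
    return m.PreparedInput(inp, schedule)


def _ode_frame_averages(model, params, inp, schedule, rtol=1e-11):
    """Independent oracle: stiff ODE integration of the compartment system.

    Augments the state with the running integral of C_pet so frame averages
    come straight from the solver, not from post-hoc quadrature.
    """
    t, cp, cwb = inp.times, inp.parent_plasma, inp.whole_blood
    K1, k2, k3, k4, vb = params.K1, params.k2, params.k3, params.k4, params.VB

    def rhs(tt, y):
        cpt = np.interp(tt, t, cp, left=0.0)
        cwbt = np.interp(tt, t, cwb, left=0.0)
        c1, c2, _ = y
        if model == "1T2k":
            d1, d2 = K1 * cpt - k2 * c1, 0.0
        else:
            d1 = K1 * cpt - (k2 + k3) * c1 + k4 * c2
            d2 = k3 * c1 - k4 * c2
        return [d1, d2, (1 - vb) * (c1 + c2) + vb * cwbt]

    bounds = np.concatenate([schedule.frame_start, schedule.frame_end[-1:]])
    sol = solve_ivp(rhs, (0.0, bounds[-1]), [0.0, 0.0, 0.0], method="LSODA",
                    rtol=rtol, atol=1e-12, t_eval=bounds, max_step=1 / 24)
    return np.diff(sol.y[2]) / schedule.frame_duration


@pytest.fixture(scope="session")
def ode_oracle():
    return _ode_frame_averages
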