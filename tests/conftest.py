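import numpy as np
import pytest

from arspk import final_model, simulate_study
from arspk.simulate import StudyDesign

SAMPLING = np.array([0.25, 0.5, 1, 2, 3, 4, 5, 6, 8, 10, 12])


@pytest.fixture(scope="session")
def model():
    """Published final model (typical values, covariate effects, variances)."""
    return final_model()


@pytest.fixture(scope="session")
def study48(model):
    """One synthetic study at the full trial design (24 + 24 subjects)."""
    return simulate_study(model, seed=2008)


@pytest.fixture(scope="session")
def tiny_study(model):
    """Six-subject study for fast estimation mechanics tests."""
    return simulate_study(model, StudyDesign(n_per_group=3), seed=42)


@pytest.fixture(scope="session")
def reduced_model(model):
    """Model with IIV on DHA clearance and F only and no covariate effects;
    cheap to refit in selection/bootstrap mechanics tests."""
    m = model.copy(preg_cl_dha=0.0, alt_f=0.0, biomass_f=0.0)
    m.omega = {"cl_ars": 0.0, "cl_dha": 0.04, "mtt": 0.0, "f": 0.0887}
    return m


def ode_oracle(k, a, b, times, x0_total=1.0):
    """Independent high-accuracy integration of the seven-state cascade."""
    from scipy.integrate import solve_ivp

    def rhs(t, x):
        return [-k * x[0],
                k * x[0] - k * x[1],
                k * x[1] - k * x[2],
                k * x[2] - k * x[3],
                k * x[3] - a * x[4],
                a * x[4] - b * x[5],
                b * x[5]]

    x0 = [x0_total, 0, 0, 0, 0, 0, 0]
    sol = solve_ivp(rhs, (0.0, float(np.max(times))), x0, t_eval=times,
                    rtol=1e-12, atol=1e-16, method="DOP853")
    return sol.y.T
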