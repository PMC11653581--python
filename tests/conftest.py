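import numpy as np
import pytest

from patchpk.nca import ConcentrationTimeProfile
from patchpk.pk_models import DoseEvent, iv_bolus_concentration
from patchpk.simulate import GK, WISTAR, simulate_rat


@pytest.fixture(scope="session")
def gk_noise_free():
    """One virtual GK rat with no measurement error or between-animal
    variability: profiles equal the closed-form model curves exactly."""
    sim = simulate_rat(GK, 1, error_cv=0.0, iiv_cv=0.0, seed=1, assay_cv=0.0)
    return sim.subjects[0]


@pytest.fixture(scope="session")
def wistar_noise_free():
    sim = simulate_rat(WISTAR, 1, error_cv=0.0, iiv_cv=0.0, seed=1, assay_cv=0.0)
    return sim.subjects[0]


def make_dense_iv_profile(dose=10.0, k_e=0.279, Vd=6.49, n_points=500, n_half_lives=10):
    """Noise-free mono-exponential IV profile densely sampled to
    ``n_half_lives`` elimination half-lives."""
    t_end = n_half_lives * np.log(2) / k_e
    t = np.linspace(1.0 / 60.0, t_end, n_points)
    c = iv_bolus_concentration(t, dose, k_e, Vd)
    return ConcentrationTimeProfile(
        subject_id="dense_iv",
        route="iv_bolus",
        times=t,
        concentrations=c,
        dose=DoseEvent(route="iv_bolus", amount=dose),
        body_weight=0.3,
    )
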