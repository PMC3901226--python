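import numpy as np
import pytest

from kinens import branched_fixture, trehalose_fixture
from kinens.model_core import evaluate_flux_profiles
from kinens.preprocessing import SmoothedProfiles


@pytest.fixture(scope="session")
def branched_noise_free():
    return branched_fixture(noise_cv=0.0)


@pytest.fixture(scope="session")
def branched_noisy():
    return branched_fixture(noise_cv=0.10, seed=42)


@pytest.fixture(scope="session")
def trehalose_noise_free():
    return trehalose_fixture(noise_model={"cv": 0.0})


def exact_profiles(model, traj, times, measured_only=True):
    """SmoothedProfiles built from an exact trajectory and exact model slopes.

    Bypasses smoothing entirely: fitted values are the true concentrations
    and slopes are S v(X_true), so incremental identification should be
    exact up to round-off.
    """
    v = evaluate_flux_profiles(model, traj)
    slopes = v @ model.stoichiometry.T
    idx = model.measured_indices if measured_only else np.arange(model.n_metabolites)
    names = [model.metabolite_names[i] for i in idx]
    m = len(idx)
    return SmoothedProfiles(times, traj[:, idx], slopes[:, idx],
                            np.zeros(m), [{"complexity": 7}] * m, names)
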