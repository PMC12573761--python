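import numpy as np
import pytest

from kinmap.toy_dynamics import (EnsembleData, LangevinParams,
                                 four_well_potential, harvest_ensemble,
                                 sample_long_trajectory)


@pytest.fixture(scope="session")
def four_well():
    return four_well_potential()


@pytest.fixture(scope="session")
def langevin_params():
    return LangevinParams()  # T=300 K, dt=0.001 ps, gamma=1/ps, m=1 amu


@pytest.fixture(scope="session")
def medium_trajectory(four_well, langevin_params):
    """2e6-step equilibrium trajectory, enough to visit all four wells."""
    return sample_long_trajectory(four_well, langevin_params, 2_000_000,
                                  np.array([-1.0, 1.0]), seed=123)


@pytest.fixture(scope="session")
def small_ensemble(medium_trajectory, four_well, langevin_params):
    """Modest four-well burst ensemble for unit-level checks."""
    return harvest_ensemble(medium_trajectory, n_states=800, stride=2500,
                            n_bursts=5, burst_steps=10,
                            potential=four_well, params=langevin_params,
                            seed=5)


@pytest.fixture(scope="session")
def ou_ensemble():
    """1D Ornstein-Uhlenbeck burst ensemble built from the exact
    propagator x_tau = x0 e^-tau + sqrt(1 - e^-2tau) xi (D = k = 1)."""
    rng = np.random.default_rng(7)
    n, m, tau = 400, 100, 0.5
    x0 = rng.normal(0.0, 1.0, (n, 1))
    decay = np.exp(-tau)
    xtau = decay * x0[:, None, :] + np.sqrt(1 - decay**2) \
        * rng.standard_normal((n, m, 1))
    return EnsembleData(X0=x0, Xtau=xtau, lag=tau, seed=7)
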