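import numpy as np
import pytest

from polecrowd import synthetic
from polecrowd.confined import FitParams, simulate_confined_msd
from polecrowd.simulate import SimConfig, build_domain, run_ensemble


@pytest.fixture(scope="session")
def lf_ensemble():
    """Default LF synthetic trajectory ensemble with truth sidecar."""
    cfg = synthetic.SynthTrajectoryConfig(seed=2024, n_per_class=40)
    return synthetic.gen_trajectories(cfg)


@pytest.fixture(scope="session")
def clean_lf_ensemble():
    """Noise-free, growth-free LF ensemble (for plateau oracles)."""
    cfg = synthetic.SynthTrajectoryConfig(seed=7, sigma_loc=0.0,
                                          growth_nm_per_s=0.0, n_per_class=120)
    return synthetic.gen_trajectories(cfg)


@pytest.fixture(scope="session")
def observed_curves():
    """Class-wise MSD curves simulated at the published truth parameters."""
    truth = FitParams()
    observed = {}
    for i, (r, D) in enumerate(zip(truth.radii, truth.D)):
        lags, mx, my = simulate_confined_msd(truth.L_X, truth.L_YZ, r, D,
                                             n_particles=5000, duration=120.0,
                                             rng=100 + i)
        observed[i] = {"lags": lags, "msd_x": mx, "msd_y": my}
    return truth, observed


@pytest.fixture(scope="session")
def nonstressed_ensemble():
    """Scaled-down non-stressed simulation ensemble (N_p = 100, p_ag = 1).

    dt = 4 us (below the 5 us stability bound) and 1e6 steps cover twice the
    2-second diffusion-limited real-time span; 48 replicates.
    """
    domain = build_domain(rng=3)
    cfg = SimConfig(n_particles=100, p_ag=1.0, dt=4e-6, n_steps=1_000_000,
                    sample_stride=20_000, seed=11)
    return run_ensemble(cfg, n_run=48, seed=2024, domain=domain), domain
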