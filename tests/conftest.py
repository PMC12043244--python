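import numpy as np
import pytest

from cncb import ConfidenceParams, SensoryParams, calibrate_boundaries


@pytest.fixture(scope="session")
def default_sens() -> SensoryParams:
    """Two-stimulus design at 75% correct: mu=+/-0.67, sigma_s=1, theta_s=0."""
    return SensoryParams(mu=np.array([-0.67, 0.67]), sigma_s=1.0, theta_s=0.0)


@pytest.fixture(scope="session")
def default_conf(default_sens) -> ConfidenceParams:
    """Default observer (sigma_c=0.5, alpha=0.2) with the single boundary
    calibrated to a 50/50 high/low split."""
    b = calibrate_boundaries(default_sens, 0.5, 0.2, [0.5, 0.5])
    return ConfidenceParams(sigma_c=0.5, alpha=0.2, boundaries=b)


@pytest.fixture(scope="session")
def six_strength_sens() -> SensoryParams:
    return SensoryParams(mu=np.array([-1.43, -0.86, -0.29, 0.29, 0.86, 1.43]))


def random_observer(rng, n_stim=2, m=4):
    """A random but well-behaved observer for property tests."""
    u = rng.uniform(0.3, 1.5)
    if n_stim == 2:
        mu = np.array([-u, u])
    else:
        mu = np.sort(rng.uniform(-2, 2, n_stim))
        while np.unique(mu).size < n_stim or np.min(np.diff(mu)) < 0.05:
            mu = np.sort(rng.uniform(-2, 2, n_stim))
    sens = SensoryParams(mu=mu, sigma_s=rng.uniform(0.5, 2.0),
                         theta_s=rng.uniform(-1.0, 1.0))
    sigma_c = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
    alpha = rng.uniform(0.0, 1.0)
    b = np.sort(rng.normal(0.8, 0.7, m - 1))
    while np.min(np.diff(b)) < 0.05 if m > 2 else False:
        b = np.sort(rng.normal(0.8, 0.7, m - 1))
    conf = ConfidenceParams(sigma_c=sigma_c, alpha=alpha, boundaries=b)
    return sens, conf


def mc_frequencies(sens, conf, n, rng):
    """Monte-Carlo relative frequencies of (decision, level) per stimulus --
    an oracle for the analytic probability table, sampled directly from the
    generative equations without using the package simulator."""
    m = conf.n_levels
    freqs = np.zeros((sens.n_stimuli, 2, m))
    for i, u in enumerate(sens.mu):
        eps_s = rng.standard_normal(n) * sens.sigma_s
        eps_c = rng.standard_normal(n) * conf.sigma_c
        s = u + eps_s
        d = np.where(s > sens.theta_s, 1, -1)
        w = (u + (1 - conf.alpha) * eps_s - sens.theta_s) / sens.sigma_s + eps_c
        lev = np.searchsorted(conf.boundaries, d * w, side="left")
        np.add.at(freqs[i], ((d > 0).astype(int), lev), 1.0)
    return freqs / n
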