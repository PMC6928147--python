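"""Shared fixtures: reference parameter sets and reusable MCMC fits.

MCMC fits are expensive, so the suite shares them at session scope: one fit
at the default noise level of the dDNP generator, and a bank of twenty
seeded replicate fits at high SNR used for calibration/coverage checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csflux import (
    AcquisitionParams,
    ExchangeParams,
    MCMCConfig,
    NoiseModel,
    fit_dnp_mcmc,
    generate_dnp_dataset,
    normalize_timecourse,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Representative fitted constants of a low-dose, fully channel-activated
# hyperpolarized experiment: T1_out 8.9 s, T1_in 1.2 s, k_fwd 0.0057 /s.
FIG2A = ExchangeParams(k_fwd=0.0057, k_rev=0.0, T1_out=8.9, T1_in=1.2)
ACQ10 = AcquisitionParams(flip_angle=10.0, rep_time=1.0, n_samples=40)

# High-SNR noise level used for the statistical-property fits: low enough
# that the intracellular build-up stands clearly above the scatter, as in
# measured integral plots.
CALIBRATION_SD = 0.001


@pytest.fixture(scope="session")
def fig2a_params() -> ExchangeParams:
    return FIG2A


@pytest.fixture(scope="session")
def acq10() -> AcquisitionParams:
    return ACQ10


def _fit_replicate(data_seed: int, sd: float, n_steps: int = 4000, **config_kw):
    ds = generate_dnp_dataset(FIG2A, ACQ10, noise=NoiseModel(sd=sd, seed=data_seed))
    tc = normalize_timecourse(ds.timecourse, "dnp_first_out", drop_first=True)
    cfg = MCMCConfig(seed=1000 + data_seed, n_steps=n_steps, **config_kw)
    return tc, fit_dnp_mcmc(tc, ACQ10, config=cfg)


@pytest.fixture(scope="session")
def dnp_default_noise_fit():
    """Full-length fit at the generator's default noise level (sd 0.005, seed 1)."""
    ds = generate_dnp_dataset(FIG2A, ACQ10, noise=NoiseModel(sd=0.005, seed=1))
    tc = normalize_timecourse(ds.timecourse, "dnp_first_out", drop_first=True)
    summary = fit_dnp_mcmc(tc, ACQ10, config=MCMCConfig(seed=2))
    return tc, summary


@pytest.fixture(scope="session")
def calibration_fits():
    """Twenty seeded replicate fits at high SNR, with their generating truth."""
    fits = []
    for data_seed in range(100, 120):
        tc, summary = _fit_replicate(data_seed, CALIBRATION_SD)
        fits.append((tc, summary))
    return fits


@pytest.fixture(scope="session")
def quick_fit():
    """One short high-SNR fit for predictive and reproducibility checks."""
    return _fit_replicate(7, CALIBRATION_SD)
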