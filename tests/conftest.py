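import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thermoresp as tr
from thermoresp import pipeline as pl

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def zero_variance_population():
    """Population with every stochastic component switched off."""
    return tr.BirdPopulation(
        mass_sd_g=0.0, psi_sd_C=0.0, fasted_sd_min=0.0,
        intercept_sd={"tb": 0.0, "rmr": 0.0, "ewl": 0.0},
        residual_sd={"tb": 0.0, "rmr": 0.0, "ewl": 0.0})


def simulate_lmm_points(seed, n_birds=20, ta_values=(35, 37, 39, 41, 43),
                        slope=0.299, intercept=31.66, intercept_sd=0.15,
                        residual_sd=0.15, mass_mean=31.0, mass_sd=2.1,
                        mass_slope=0.0):
    """Point-level draw from a random-intercept linear model (column 'y')."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_birds):
        u = rng.normal(0, intercept_sd) if intercept_sd else 0.0
        m = mass_mean + (rng.normal(0, mass_sd) if mass_sd else 0.0)
        for t in ta_values:
            rows.append({
                "bird_id": f"b{b:03d}", "Ta_C": float(t), "mass_g": m,
                "y": (intercept + slope * t + mass_slope * m + u
                      + (rng.normal(0, residual_sd) if residual_sd else 0.0)),
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def mean_bird():
    """A single bird with parameters exactly at the population means."""
    return tr.sample_birds(1, zero_variance_population(), seed=0)[0]


@pytest.fixture(scope="session")
def noiseless_session(mean_bird):
    """Deterministic session: no noise, no drift, no residual variation."""
    return tr.simulate_session(mean_bird, noise=tr.SessionNoise.zero())


@pytest.fixture(scope="session")
def study_points():
    """Reduced physiological points for a small simulated study (10 birds)."""
    cfg = pl.PipelineConfig(n_birds=10, seed=7)
    points, _ = pl.reduce_sessions(pl.simulate_study(cfg), cfg)
    return points
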