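"""Shared fixtures: simulated cohorts and rendered IHC tiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ihcstrat import SimConfig, simulate_cohort
from ihcstrat.synthetic import DEFAULT_STAIN_MATRIX, render_ihc_tile


@pytest.fixture(scope="session")
def sep8_cohort():
    """50 patients x 20 tiles at separation 8: the high-recovery regime."""
    cfg = SimConfig(
        n_patients_per_cohort=25,
        tiles_per_patient=(20, 20),
        cluster_separation=8.0,
        noise_sd=1.0,
        latent_dim=5,
        censoring_rate=0.2,
        seed=1,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def paperlike_cohort():
    """Discovery-set tile density like the study's (~70 tiles/patient)."""
    cfg = SimConfig(
        n_patients_per_cohort=50,
        tiles_per_patient=(50, 90),
        cluster_separation=8.0,
        noise_sd=1.0,
        latent_dim=5,
        censoring_rate=0.2,
        seed=2,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for plumbing tests (64 features)."""
    cfg = SimConfig(
        n_patients_per_cohort=40,
        tiles_per_patient=(5, 10),
        n_features=64,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_stain_tile():
    """Well-mixed two-chromogen tile rendered with the known stain matrix."""
    rng = np.random.default_rng(11)
    n = 96
    u = rng.uniform(0, 1, (n, n))
    base = rng.uniform(0.5, 1.5, (n, n))
    c1 = 1.5 * u * base
    c2 = 1.5 * (1 - u) * base
    img = render_ihc_tile(DEFAULT_STAIN_MATRIX, [c1, c2], 255)
    return img, (c1, c2), DEFAULT_STAIN_MATRIX


def exp_survival_frame(n, rng, rate=0.2, group_beta=0.0, censor_upper=None):
    """Plain exponential survival frame with an optional binary group effect."""
    g = rng.binomial(1, 0.5, n)
    lam = rate * np.exp(group_beta * g)
    t = rng.exponential(1.0 / lam)
    event = np.ones(n, int)
    if censor_upper is not None:
        c = rng.uniform(0, censor_upper, n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "time_months": t,
            "event": event,
            "group": np.where(g == 1, "B", "A"),
        }
    )
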