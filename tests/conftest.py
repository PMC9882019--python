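"""Shared fixtures: task variants, the worked toy pair, and reusable cohort fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from occam.manifolds import NoiseModel, PointManifold, SegmentManifold
from occam.sensitivity import DELTA_COLUMNS, build_design, fit_hierarchical
from occam.taskgen import default_variants, sample_trials


@pytest.fixture(scope="session")
def variants():
    return default_variants()


@pytest.fixture(scope="session")
def variant_map(variants):
    return {v.name: v for v in variants}


@pytest.fixture(scope="session")
def toy_pair():
    """Point at the origin vs unit segment at height 1, unit noise, one datum."""
    m1 = PointManifold((0.0, 0.0), label="simple")
    m2 = SegmentManifold((-0.5, 1.0), (0.5, 1.0), label="complex")
    return (m1, m2), NoiseModel(sigma=1.0, n_obs=1)


def plant_logistic_cohort(
    variants, beta_mean, beta_scale, n_per_variant, n_trials, seed, lapse=0.0
):
    """Cohort of choices drawn from the hierarchical logistic model itself."""
    rng = np.random.default_rng(seed)
    frames = []
    pid = 0
    for v in variants:
        for _ in range(n_per_variant):
            beta = np.asarray(beta_mean) + np.asarray(beta_scale) * rng.standard_normal(6)
            batch = sample_trials(v, n_trials, rng)
            d = build_design(v, batch, None, f"p{pid:03d}")
            pid += 1
            X = np.column_stack([np.ones(len(d)), d[list(DELTA_COLUMNS)].to_numpy()])
            p_up = lapse / 2.0 + (1.0 - lapse) * expit(X @ beta)
            d["choice_up"] = (rng.random(len(d)) < p_up).astype(int)
            frames.append((d, beta))
    designs = pd.concat([f for f, _ in frames], ignore_index=True)
    designs.attrs["planted"] = np.array([b for _, b in frames])
    return designs


HUMANLIKE = np.array([0.0, 1.0, 4.66, 1.12, 0.23, 2.21])
ZERO_FIA = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
PLANT_SCALE = np.array([0.1, 0.1, 0.5, 0.15, 0.1, 0.3])


@pytest.fixture(scope="session")
def humanlike_designs(variants):
    return plant_logistic_cohort(variants, HUMANLIKE, PLANT_SCALE, 3, 150, seed=101)


@pytest.fixture(scope="session")
def humanlike_fit(humanlike_designs):
    return fit_hierarchical(humanlike_designs, chains=4, n_warmup=800, n_draws=800, seed=7)


@pytest.fixture(scope="session")
def zero_designs(variants):
    return plant_logistic_cohort(variants, ZERO_FIA, PLANT_SCALE, 3, 150, seed=202)


@pytest.fixture(scope="session")
def zero_fit(zero_designs):
    return fit_hierarchical(zero_designs, chains=4, n_warmup=800, n_draws=800, seed=8)
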