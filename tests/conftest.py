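"""Shared fixtures: small synthetic landscapes and tabular use-availability
designs cheap enough for MCMC in unit tests."""

import numpy as np
import pandas as pd
import pytest

from rsfkit import landscape as land
from rsfkit.design import DesignMatrix


@pytest.fixture(scope="session")
def small_landscape():
    """A 60 x 60-cell (1.8 km) landscape with a carved shrub-loss epoch."""
    cfg = land.LandscapeConfig(extent=(0.0, 0.0, 1800.0, 1800.0))
    scape = land.generate_landscape(cfg, seed=42)
    land.generate_shrub_epochs(scape, loss_magnitude=8.0, loss_radius=500.0)
    return scape


@pytest.fixture(scope="session")
def small_truth():
    return land.SimulationTruth(
        beta={"shrub": 1.0, "rugged": -0.8, "elevation": -0.4,
              "northness": 0.2, "road": -0.3, "water": 0.2, "mesic": 0.4},
        true_scale={"shrub": 331.0, "rugged": 331.0},
        re_sd=0.3,
        release_effect=0.6,
    )


def make_tabular_design(n_used_train=150, n_used_test=75, ratio=5,
                        beta=(1.0, -0.5), seed=0, pool_factor=40,
                        extra_noise_cols=0):
    """A use-availability design with no spatial machinery.

    Availability rows are standard-normal covariates; used rows are drawn
    from a large availability pool with probability proportional to
    exp(x'beta) — the exponential RSF's own generative story — so a model
    fitted with the same columns is correctly specified by construction.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    k = beta.size + extra_noise_cols
    cols = [f"v{i}" for i in range(k)]
    frames = []
    for split, n_used in (("train", n_used_train), ("test", n_used_test)):
        pool = rng.standard_normal((pool_factor * n_used, k))
        w = np.exp(pool[:, :beta.size] @ beta)
        used_idx = rng.choice(len(pool), size=n_used, p=w / w.sum())
        avail_idx = rng.choice(len(pool), size=ratio * n_used)
        X = np.vstack([pool[used_idx], pool[avail_idx]])
        df = pd.DataFrame(X, columns=cols)
        df["used"] = [1] * n_used + [0] * ratio * n_used
        df["split"] = split
        df["individual_id"] = [f"{split}_{i % 10}" for i in range(len(df))]
        df["pair_id"] = 0
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    return DesignMatrix(df=df, covariate_columns=cols, scale_groups={},
                        scaling=None, alphas={}, season="test")


@pytest.fixture()
def tabular_design():
    return make_tabular_design(seed=3)
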