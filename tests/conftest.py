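import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from udsamp.simulate import preset_config, simulate_experiment


def make_glmm_data(seed, n_groups=50, per_group=6, beta=(0.0,),
                   sd_group=0.7, trials=1, x=None, crossed_objects=0,
                   sd_object=0.0):
    """Simulate directly from a (possibly crossed) logistic mixed model."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    gidx = np.repeat(np.arange(n_groups), per_group)
    cols = {"participant": gidx}
    eta = np.full(n, float(beta[0]))
    if len(beta) > 1:
        if x is None:
            x = rng.binomial(1, 0.5, n).astype(float)
        eta = eta + beta[1] * x
        cols["x"] = x
    b = rng.normal(0.0, sd_group, n_groups)
    eta = eta + b[gidx]
    if crossed_objects:
        oidx = np.tile(np.arange(crossed_objects),
                       n // crossed_objects + 1)[:n]
        eta = eta + rng.normal(0.0, sd_object, crossed_objects)[oidx]
        cols["object"] = oidx
    y = rng.binomial(trials, expit(eta)).astype(float)
    cols["y"] = y
    if trials > 1:
        cols["succ"] = y
        cols["fail"] = trials - y
    return pd.DataFrame(cols)


@pytest.fixture(scope="session")
def adult_tables():
    """One adult-preset simulated dataset (n = 40), reused read-only."""
    cfg = preset_config(groups=("adult",), n_per_group=40, seed=2024)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_tables():
    """Tiny 2-participant dataset for schema-level tests."""
    cfg = preset_config(groups=("adult",), n_per_group=2, seed=7)
    return simulate_experiment(cfg)
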