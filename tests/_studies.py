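"""Replicated simulation studies shared by several acceptance tests.

Each study is cached so that multiple criteria (e.g. permutation validity
and the Wald-inflation check) reuse a single run.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from udsamp import analyses as an
from udsamp.glmm import wald_test
from udsamp.simulate import preset_config, simulate_experiment, substream


@lru_cache(maxsize=4)
def sampling_null_study(w: float, n_reps: int, n_perm: int,
                        n_participants: int = 50, master_seed: int = 101):
    """Replicated adult-preset study of the two-column sampling model.

    Returns arrays of (naive Wald p, permutation p, judgement estimate).
    """
    wald_p, perm_p, ests = [], [], []
    for rep in range(n_reps):
        cfg = preset_config(
            groups=("adult",), n_per_group=n_participants,
            seed=int(substream(master_seed, "sim", rep)
                     .integers(0, 2**31 - 1)))
        cfg.group_overrides["adult"]["sampling_preference_w"] = w
        records, _ = simulate_experiment(cfg)
        rows = an.build_sampling_matrix(records)
        perm = an.permutation_test_sampling(
            rows, n_perm=n_perm,
            seed=int(substream(master_seed, "perm", rep)
                     .integers(0, 2**31 - 1)))
        wald_p.append(
            wald_test(perm.observed_fit, "knowledge_judgement").p_value)
        perm_p.append(perm.p_value)
        ests.append(perm.observed_fit.estimates["knowledge_judgement"])
    return np.array(wald_p), np.array(perm_p), np.array(ests)
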