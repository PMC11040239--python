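"""Beta regression with a logit mean link for responses strictly in (0, 1).

Thin wrapper around :class:`statsmodels.othermod.betareg.BetaModel` that
returns the package-wide :class:`~udsamp.glmm.FitResult` so Wald tests and
report writers treat fixed-effect-only beta fits and mixed logistic fits
uniformly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

from udsamp.glmm import FitResult, _INTERCEPT, _column

__all__ = ["fit_beta_glm"]


def fit_beta_glm(table: pd.DataFrame, response_column: str,
                 fixed_terms=()) -> FitResult:
    """Maximum-likelihood beta regression (logit mean link, log precision).

    The response must lie strictly inside (0, 1); boundary values indicate
    that upstream exclusions were skipped and raise immediately.
    """
    y = pd.to_numeric(table[response_column]).to_numpy(dtype=float)
    if len(y) == 0:
        raise ValueError("cannot fit a beta regression to an empty table")
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError(
            f"response {response_column!r} must be strictly inside (0, 1); "
            "exclude boundary observations upstream"
        )
    fixed_terms = tuple(fixed_terms)
    names = (_INTERCEPT,) + fixed_terms
    X = np.column_stack([np.ones(len(y))]
                        + [_column(table, t) for t in fixed_terms])

    model = BetaModel(y, X)
    res = model.fit(disp=False)
    if not res.mle_retvals.get("converged", True):
        res = model.fit(method="bfgs", maxiter=500, disp=False,
                        start_params=res.params)
    k = X.shape[1]
    estimates = dict(zip(names, map(float, res.params[:k])))
    ses = dict(zip(names, map(float, res.bse[:k])))
    precision = float(np.exp(res.params[k]))  # precision is log-linked

    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        varcomps={"precision": np.array([[precision]])},
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        singular=False,
        separation=False,
        non_estimable=(),
        n_obs=len(y),
        n_groups={},
        theta=np.array([np.log(precision)]),
        spec=None,
        _model=None,
    )
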