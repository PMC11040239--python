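"""Independent oracles used by the test suite.

These deliberately share no code with the package's fitting paths:

* an adaptive Gauss-Hermite maximum-likelihood fitter for single-factor
  random-intercept logistic models (brute-force marginal likelihood);
* exact enumeration of Plackett-Luce inclusion probabilities for
  sequential weighted sampling without replacement, and the two-column
  model estimand they induce.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats
from scipy.special import expit


def agh_loglik(params, y, n, X, gidx, n_groups, nodes=31):
    """Adaptive Gauss-Hermite marginal log-likelihood (probabilists'
    nodes, mode-centred and curvature-scaled per group)."""
    beta, logsd = np.asarray(params[:-1]), params[-1]
    sd = np.exp(logsd)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(nodes)
    eta0 = X @ beta
    ll = 0.0
    for g in range(n_groups):
        sel = gidx == g
        e0, yg, ng = eta0[sel], y[sel], n[sel]

        def neg_joint(b):
            eta = e0 + b
            return -(yg @ eta - ng @ np.logaddexp(0.0, eta)
                     - 0.5 * b * b / sd**2)

        res = optimize.minimize_scalar(neg_joint, bounds=(-15, 15),
                                       method="bounded",
                                       options={"xatol": 1e-11})
        bhat = res.x
        mu = expit(e0 + bhat)
        curv = np.sum(ng * mu * (1 - mu)) + 1.0 / sd**2
        scale = 1.0 / np.sqrt(curv)
        b = bhat + scale * gh_x
        etas = e0[None, :] + b[:, None]
        logf = (etas @ yg - np.logaddexp(0.0, etas) @ ng
                - 0.5 * (b / sd) ** 2 - np.log(sd)
                - 0.5 * np.log(2 * np.pi))
        logterms = logf + 0.5 * gh_x**2 + np.log(scale)
        m = logterms.max()
        ll += m + np.log(np.sum(gh_w * np.exp(logterms - m)))
    ll += float(np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                       - special.gammaln(n - y + 1)))
    return ll


def agh_fit_deviance(y, n, X, gidx, n_groups, nodes=31):
    """Deviance (-2 loglik) of the quadrature-based ML fit."""
    res = optimize.minimize(
        lambda p: -agh_loglik(p, y, n, X, gidx, n_groups, nodes),
        np.concatenate([np.zeros(X.shape[1]), [np.log(0.5)]]),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 20000})
    return 2.0 * res.fun, res.x


def pl_inclusion_probs(weights, k):
    """Exact inclusion probability of each item in k sequential
    Plackett-Luce draws without replacement."""
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    probs = np.zeros(n)

    def rec(remaining, p, chosen):
        if len(chosen) == k:
            for c in chosen:
                probs[c] += p
            return
        tot = sum(weights[j] for j in remaining)
        for j in list(remaining):
            rec(remaining - {j}, p * weights[j] / tot, chosen + [j])

    rec(frozenset(range(n)), 1.0, [])
    return probs


def induced_judgement_coefficient(w, p_unknown, n_objects=6, n_choices=3):
    """Estimand of the two-column model's judgement coefficient under the
    generator: logit contrast of expected per-object sampling proportions,
    averaging over the binomial distribution of the judged-unknown count.

    Sign convention matches the model coding (judgement 1 = known), so the
    returned value is negative when unknown objects are preferred.
    """
    ks = np.arange(0, n_objects + 1)
    pk = stats.binom.pmf(ks, n_objects, p_unknown)
    num_u = den_u = num_k = den_k = 0.0
    for k, p in zip(ks, pk):
        if k in (0, n_objects):
            # uniform weights: every object included with prob k_choices/n
            pi = np.full(n_objects, n_choices / n_objects)
        else:
            wts = np.array([np.exp(w)] * k + [1.0] * (n_objects - k))
            pi = pl_inclusion_probs(wts, n_choices)
        num_u += p * pi[:k].sum()
        den_u += p * k
        num_k += p * pi[k:].sum()
        den_k += p * (n_objects - k)
    p_u = num_u / den_u / n_choices
    p_kn = num_k / den_k / n_choices
    return float(np.log(p_kn / (1 - p_kn)) - np.log(p_u / (1 - p_u)))
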