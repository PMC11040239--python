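"""Logistic mixed models with crossed random effects, fitted by Laplace
approximation, plus the Wald / likelihood-ratio machinery built on top.

The marginal likelihood integrates normally distributed random effects out
of a binomial-logit (optionally aggregated two-column) response.  Random
effects are parameterized through per-term Cholesky factors so that
variance components can reach the boundary (zero variance) without the
optimizer leaving its domain; a boundary fit is flagged ``singular`` rather
than silently accepted.

Only binomial-logit responses are handled here; beta-logit regression for
proportions lives in :mod:`udsamp.beta`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "TestResult",
    "logit",
    "inv_logit",
    "z_standardize",
    "fit_logistic_mixed",
    "refit",
    "simulate_response",
    "wald_test",
    "likelihood_ratio_test",
    "NonEstimableError",
]

_INTERCEPT = "intercept"

# Laplace fits whose diagonal Cholesky entries fall below this (on the
# logit scale) are treated as boundary/singular.
_SINGULAR_SD = 1e-3

# |estimate| beyond this on the log-odds scale is taken as quasi-complete
# separation: the likelihood is flat and no finite MLE exists.
_SEPARATION_BOUND = 12.0


class NonEstimableError(ValueError):
    """A requested term cannot be estimated from the supplied data."""


def logit(p):
    """Natural log-odds of a probability strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires probabilities strictly in (0, 1)")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Inverse of :func:`logit`; maps any real number into (0, 1)."""
    out = special.expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def z_standardize(values) -> np.ndarray:
    """Affinely rescale ``values`` to sample mean 0 and sample s.d. 1.

    Uses the n-1 denominator.  Raises :class:`NonEstimableError` for
    constant input, which would make the rescaled predictor undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise NonEstimableError("z-standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise NonEstimableError("cannot z-standardize a constant predictor")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a binomial-logit mixed model.

    Parameters
    ----------
    response
        Either a single binary column name, or a ``(successes, failures)``
        pair of column names for an aggregated two-column response.
    fixed_terms
        Predictor column names (the intercept is implicit).  A term of the
        form ``"a:b"`` denotes the elementwise product of columns a and b.
    random_terms
        ``(grouping_factor, slope_columns)`` pairs; an empty slope list
        gives a random intercept only, otherwise intercept + slopes with a
        fully parameterized covariance.
    """

    response: str | tuple[str, str]
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[tuple[str, tuple[str, ...]], ...] = ()
    family: str = "binomial"

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(
            self,
            "random_terms",
            tuple((g, tuple(s)) for g, s in self.random_terms),
        )
        if self.family != "binomial":
            raise ValueError(f"unsupported family {self.family!r}")
        for _, slopes in self.random_terms:
            for s in slopes:
                if s not in self.fixed_terms:
                    raise ValueError(
                        f"random slope {s!r} is not among the fixed terms"
                    )

    def to_dict(self) -> dict:
        return {
            "response": (list(self.response)
                         if isinstance(self.response, tuple)
                         else self.response),
            "fixed_terms": list(self.fixed_terms),
            "random_terms": [[g, list(s)] for g, s in self.random_terms],
            "family": self.family,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        response = d["response"]
        if isinstance(response, (list, tuple)):
            response = tuple(response)
        return cls(
            response=response,
            fixed_terms=tuple(d.get("fixed_terms", ())),
            random_terms=tuple(
                (g, tuple(s)) for g, s in d.get("random_terms", ())),
            family=d.get("family", "binomial"),
        )


@dataclass
class FitResult:
    """Converged (or diagnosed) state of a mixed-model fit."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    varcomps: dict[str, np.ndarray]
    loglik: float
    converged: bool
    singular: bool
    separation: bool
    non_estimable: tuple[str, ...]
    n_obs: int
    n_groups: dict[str, int]
    theta: np.ndarray
    spec: ModelSpec | None = None
    _model: "object | None" = field(default=None, repr=False)

    @property
    def n_fixed(self) -> int:
        return len(self.estimates)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for term, est in self.estimates.items():
            se = self.standard_errors.get(term, math.nan)
            z = est / se if se and se > 0 else math.nan
            p = 2.0 * stats.norm.sf(abs(z)) if not math.isnan(z) else math.nan
            rows.append({"term": term, "estimate": est, "se": se,
                         "statistic": z, "p": p})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# design construction


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a fixed-term name, supporting ':' products."""
    parts = name.split(":")
    out = np.ones(len(table))
    for p in parts:
        if p not in table.columns:
            raise KeyError(f"column {p!r} not found in table")
        out = out * pd.to_numeric(table[p]).to_numpy(dtype=float)
    return out


class _RandomTerm:
    __slots__ = ("name", "labels", "idx", "n_groups", "q", "S", "slope_names")

    def __init__(self, table, factor, slopes):
        if factor not in table.columns:
            raise KeyError(f"grouping factor {factor!r} not found in table")
        codes, labels = pd.factorize(table[factor], sort=True)
        self.name = factor
        self.labels = labels
        self.idx = codes.astype(np.int64)
        self.n_groups = len(labels)
        self.q = 1 + len(slopes)
        cols = [np.ones(len(table))]
        cols += [_column(table, s) for s in slopes]
        self.S = np.column_stack(cols)
        self.slope_names = (_INTERCEPT,) + tuple(slopes)


class MixedLogitModel:
    """Design matrices plus the Laplace-likelihood engine for one dataset.

    The object is reusable: :meth:`fit` accepts a replacement response
    vector, which keeps permutation tests and parametric bootstraps cheap
    because nothing about the design has to be rebuilt.
    """

    def __init__(self, spec: ModelSpec, table: pd.DataFrame):
        if len(table) == 0:
            raise ValueError("cannot fit a model to an empty table")
        self.spec = spec
        self.n = len(table)

        if isinstance(spec.response, tuple):
            succ = pd.to_numeric(table[spec.response[0]]).to_numpy(float)
            fail = pd.to_numeric(table[spec.response[1]]).to_numpy(float)
            if np.any(succ < 0) or np.any(fail < 0):
                raise ValueError("two-column response must be non-negative")
            self.y = succ
            self.ntrials = succ + fail
        else:
            y = pd.to_numeric(table[spec.response]).to_numpy(float)
            if not np.isin(y, (0.0, 1.0)).all():
                raise ValueError(
                    f"binary response {spec.response!r} must be coded 0/1"
                )
            self.y = y
            self.ntrials = np.ones(self.n)

        self.fixed_names = (_INTERCEPT,) + tuple(spec.fixed_terms)
        cols = [np.ones(self.n)] + [_column(table, t) for t in spec.fixed_terms]
        self.X = np.column_stack(cols)
        self.p = self.X.shape[1]

        self.non_estimable: list[str] = []
        # rank check: drop-rank columns are flagged, not silently dropped
        if np.linalg.matrix_rank(self.X) < self.p:
            for j, name in enumerate(self.fixed_names):
                others = np.delete(self.X, j, axis=1)
                resid = self.X[:, j] - others @ np.linalg.lstsq(
                    others, self.X[:, j], rcond=None)[0]
                if np.max(np.abs(resid)) < 1e-10:
                    self.non_estimable.append(name)
        for j, name in enumerate(self.fixed_names[1:], start=1):
            if np.ptp(self.X[:, j]) == 0.0:
                if name not in self.non_estimable:
                    self.non_estimable.append(name)

        self.terms = [_RandomTerm(table, g, s) for g, s in spec.random_terms]
        for t in self.terms:
            if t.n_groups < 2:
                raise ValueError(
                    f"grouping factor {t.name!r} needs at least 2 levels"
                )
        self.q_total = sum(t.n_groups * t.q for t in self.terms)

        # per random-effect column: global column index array and raw design
        offs = 0
        self._cols: list[np.ndarray] = []
        self._col_term: list[tuple[int, int]] = []  # (term index, coord)
        for ti, t in enumerate(self.terms):
            for k in range(t.q):
                self._cols.append(offs + t.idx * t.q + k)
                self._col_term.append((ti, k))
            offs += t.n_groups * t.q
        self._theta_slices = []
        pos = 0
        for t in self.terms:
            npar = t.q * (t.q + 1) // 2
            self._theta_slices.append(slice(pos, pos + npar))
            pos += npar
        self.n_theta = pos
        self._binom_const = float(
            np.sum(special.gammaln(self.ntrials + 1)
                   - special.gammaln(self.y + 1)
                   - special.gammaln(self.ntrials - self.y + 1))
        )
        # flattened scatter indices for the q x q curvature block, fixed
        # across evaluations
        q = self.q_total
        self._pair_idx = [
            [c1 * q + c2 for c2 in self._cols] for c1 in self._cols
        ]
        self._warm: tuple[np.ndarray, np.ndarray] | None = None

    # -- theta helpers ----------------------------------------------------

    def theta_init(self) -> np.ndarray:
        theta = np.zeros(self.n_theta)
        for t, sl in zip(self.terms, self._theta_slices):
            block = np.zeros(sl.stop - sl.start)
            # diagonal entries (log scale) come first within each block
            block[: t.q] = math.log(0.5)
            theta[sl] = block
        return theta

    def _cholesky(self, theta_block: np.ndarray, q: int) -> np.ndarray:
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(theta_block[:q])
        if q > 1:
            L[np.tril_indices(q, -1)] = theta_block[q:]
        return L

    def cholesky_factors(self, theta) -> list[np.ndarray]:
        return [
            self._cholesky(np.asarray(theta)[sl], t.q)
            for t, sl in zip(self.terms, self._theta_slices)
        ]

    def _effective_designs(self, theta) -> list[np.ndarray]:
        """Per random-effect column, the row design S @ L (n-vectors)."""
        meffs = []
        for t, sl in zip(self.terms, self._theta_slices):
            L = self._cholesky(np.asarray(theta)[sl], t.q)
            SL = t.S @ L  # n x q
            meffs.extend(SL[:, k] for k in range(t.q))
        return meffs

    # -- penalized IRLS (joint Newton over beta, u) -----------------------

    def _penalized(self, beta, u, meffs):
        eta = self.X @ beta
        for cols, m in zip(self._cols, meffs):
            eta = eta + m * u[cols]
        ll = float(self.y @ eta - self.ntrials @ np.logaddexp(0.0, eta))
        return eta, ll - 0.5 * float(u @ u)

    def _weights_resid(self, eta):
        mu = special.expit(eta)
        w = self.ntrials * mu * (1.0 - mu) + 1e-12
        r = self.y - self.ntrials * mu
        return w, r

    def _huu(self, w, meffs):
        q, ncol = self.q_total, len(self._cols)
        Huu = np.zeros(q * q)
        for j1 in range(ncol):
            wm1 = w * meffs[j1]
            for j2 in range(ncol):
                Huu += np.bincount(self._pair_idx[j1][j2],
                                   weights=wm1 * meffs[j2],
                                   minlength=q * q)
        Huu = Huu.reshape(q, q)
        Huu[np.diag_indices(q)] += 1.0
        return Huu

    def _beta_blocks(self, w, meffs):
        q, p = self.q_total, self.p
        Hxx = (self.X * w[:, None]).T @ self.X
        Hxu = np.zeros((p, q))
        for c1, m1 in zip(self._cols, meffs):
            wm1 = w * m1
            for a in range(p):
                Hxu[a] += np.bincount(c1, weights=wm1 * self.X[:, a],
                                      minlength=q)
        return Hxx, Hxu

    def _pirls(self, theta, beta, u, *, profile_beta, tol=1e-10, maxiter=80):
        """Newton ascent of the penalized log-likelihood.

        With ``profile_beta`` the fixed effects are updated jointly with the
        random-effect modes (cheap, slightly approximate); otherwise beta is
        held fixed and only the modes ``u`` are located.
        """
        meffs = self._effective_designs(theta)
        q, p = self.q_total, self.p
        eta, h = self._penalized(beta, u, meffs)
        converged = False
        Huu_pen = None
        for _ in range(maxiter):
            w, r = self._weights_resid(eta)
            gu = -u.copy()
            for cols, m in zip(self._cols, meffs):
                gu += np.bincount(cols, weights=m * r, minlength=q)
            Huu_pen = self._huu(w, meffs)
            if profile_beta:
                gb = self.X.T @ r
                gnorm = max(np.max(np.abs(gb)), np.max(np.abs(gu)))
            else:
                gnorm = np.max(np.abs(gu))
            if gnorm < tol * max(1.0, abs(h)):
                converged = True
                break

            if profile_beta:
                Hxx, Hxu = self._beta_blocks(w, meffs)
                A = np.empty((p + q, p + q))
                A[:p, :p] = Hxx
                A[:p, p:] = Hxu
                A[p:, :p] = Hxu.T
                A[p:, p:] = Huu_pen
                g = np.concatenate([gb, gu])
            else:
                A, g = Huu_pen, gu
            try:
                step = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, g, rcond=None)[0]
            # step-halving keeps the penalized objective monotone
            scale = 1.0
            for _ in range(30):
                if profile_beta:
                    beta_n = beta + scale * step[:p]
                    u_n = u + scale * step[p:]
                else:
                    beta_n = beta
                    u_n = u + scale * step
                eta_n, h_n = self._penalized(beta_n, u_n, meffs)
                if h_n >= h - 1e-12:
                    break
                scale *= 0.5
            if h_n < h - 1e-8:
                break  # no ascent possible
            improved = h_n - h
            beta, u, eta, h = beta_n, u_n, eta_n, h_n
            if improved < 1e-13 * max(1.0, abs(h)):
                converged = True
                break
        if Huu_pen is None:  # pragma: no cover - maxiter 0 guard
            raise RuntimeError("PIRLS produced no curvature matrix")
        return beta, u, h, Huu_pen, meffs, converged

    def laplace_loglik(self, theta, beta=None, *, warm=True):
        """Laplace-approximate marginal log-likelihood.

        When ``beta`` is None the fixed effects are profiled inside the
        penalized Newton iteration (the fast approximation); otherwise the
        likelihood is evaluated at the supplied fixed effects with only the
        random-effect modes optimized.
        """
        beta0, u = self._start(warm)
        profile = beta is None
        if not profile:
            beta0 = np.asarray(beta, dtype=float)
        beta_h, u, h, Huu_pen, _, ok = self._pirls(theta, beta0, u,
                                                   profile_beta=profile)
        if warm:
            self._warm = (beta_h.copy(), u.copy())
        sign, logdet = np.linalg.slogdet(Huu_pen)
        if sign <= 0:
            return -np.inf, beta_h, u, ok
        ll = h + self._binom_const - 0.5 * logdet
        return ll, beta_h, u, ok

    def _start(self, warm):
        if warm and self._warm is not None:
            return self._warm[0].copy(), self._warm[1].copy()
        ybar = np.clip(self.y.sum() / max(self.ntrials.sum(), 1.0), 1e-3,
                       1 - 1e-3)
        beta = np.zeros(self.p)
        beta[0] = math.log(ybar / (1 - ybar))
        return beta, np.zeros(self.q_total)

    # -- public fitting interface ----------------------------------------

    def set_response(self, y: np.ndarray) -> None:
        """Swap in a replacement response vector (same design)."""
        y = np.asarray(y, dtype=float)
        if y.shape != self.y.shape:
            raise ValueError("replacement response has wrong length")
        self.y = y
        self._binom_const = float(
            np.sum(special.gammaln(self.ntrials + 1)
                   - special.gammaln(self.y + 1)
                   - special.gammaln(self.ntrials - self.y + 1))
        )
        self._warm = None

    def degenerate_response(self) -> bool:
        return bool(np.all(self.y == 0) or np.all(self.y == self.ntrials))

    def fit(self, y: np.ndarray | None = None, theta0=None, *,
            outer_maxiter=200, fast=False) -> FitResult:
        if y is not None:
            self.set_response(y)
        self._warm = None

        if self.degenerate_response():
            return self._degenerate_result()

        theta0 = self.theta_init() if theta0 is None else np.asarray(
            theta0, dtype=float).copy()
        bounds = []
        for t, sl in zip(self.terms, self._theta_slices):
            bounds += [(-8.0, 4.0)] * t.q
            bounds += [(-8.0, 8.0)] * (sl.stop - sl.start - t.q)
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

        def nll_profiled(theta):
            ll, *_ = self.laplace_loglik(theta)
            return 1e10 if not np.isfinite(ll) else -ll

        # stage 0: fast profiled-beta fit over theta only
        if self.n_theta == 0:
            theta = theta0
            stage0_ok = True
        else:
            opts = {"maxiter": 15 if fast else 100,
                    "ftol": 1e-7 if fast else 1e-10, "gtol": 1e-6,
                    "eps": 1e-5}
            res = optimize.minimize(nll_profiled, theta0, method="L-BFGS-B",
                                    bounds=bounds, options=opts)
            theta = np.asarray(res.x, dtype=float)
            stage0_ok = bool(res.success) or res.status == 1
            if not stage0_ok:
                # FD-gradient noise can abort the line search near the
                # optimum; a short simplex run is robust to it
                res2 = optimize.minimize(
                    nll_profiled, theta, method="Nelder-Mead",
                    options={"xatol": 1e-5, "fatol": 1e-7,
                             "maxfev": 80 * max(1, self.n_theta)})
                if res2.fun <= res.fun:
                    theta = np.asarray(res2.x, dtype=float)
                    stage0_ok = bool(res2.success)
        self._warm = None
        ll, beta, u, inner_ok = self.laplace_loglik(theta, warm=False)
        res_ok = stage0_ok

        if not fast:
            # stage 1: exact Laplace objective over (theta, beta) jointly
            beta_bounds = [(-25.0, 25.0)] * self.p
            z0 = np.concatenate([theta, beta])

            def nll_joint(z):
                ll, *_ = self.laplace_loglik(z[: self.n_theta],
                                             z[self.n_theta:])
                return 1e10 if not np.isfinite(ll) else -ll

            res = optimize.minimize(
                nll_joint, z0, method="L-BFGS-B",
                bounds=bounds + beta_bounds,
                options={"maxiter": outer_maxiter, "ftol": 1e-11,
                         "gtol": 1e-6, "eps": 1e-5})
            res_ok = bool(res.success) or res.status == 1
            # simplex polish: cleans up FD-gradient noise near boundaries
            res2 = optimize.minimize(
                nll_joint, res.x, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10,
                         "maxfev": 500 * len(res.x) if not res.success
                         else 120 * len(res.x)})
            if res2.fun <= res.fun:
                res, res_ok = res2, res_ok or bool(res2.success)
            theta = np.asarray(res.x[: self.n_theta], dtype=float)
            beta = np.asarray(res.x[self.n_theta:], dtype=float)
            self._warm = None
            ll, _, u, inner_ok = self.laplace_loglik(theta, beta, warm=False)

        # curvature blocks at the optimum, for Wald standard errors
        _, u, h, Huu_pen, meffs, _ = self._pirls(theta, beta, u,
                                                 profile_beta=False)
        eta = self.X @ beta
        for cols, m in zip(self._cols, meffs):
            eta = eta + m * u[cols]
        w, _ = self._weights_resid(eta)
        Hxx, Hxu = self._beta_blocks(w, meffs)

        ses = self._wald_se(theta, beta, Hxx, Hxu, Huu_pen, exact=not fast)

        singular = False
        varcomps: dict[str, np.ndarray] = {}
        for t, sl in zip(self.terms, self._theta_slices):
            L = self._cholesky(theta[sl], t.q)
            varcomps[t.name] = L @ L.T
            if np.any(np.diag(L) < _SINGULAR_SD):
                singular = True
            if t.q > 1:
                d = np.sqrt(np.clip(np.diag(varcomps[t.name]), 1e-300, None))
                corr = varcomps[t.name] / np.outer(d, d)
                off = corr[np.tril_indices(t.q, -1)]
                if np.any(np.abs(off) > 0.999):
                    singular = True

        separation = bool(np.any(np.abs(beta) > _SEPARATION_BOUND))
        estimates = dict(zip(self.fixed_names, map(float, beta)))
        serrs = dict(zip(self.fixed_names, map(float, ses)))
        non_est = list(self.non_estimable)
        if separation:
            for name, est in estimates.items():
                if abs(est) > _SEPARATION_BOUND and name not in non_est:
                    non_est.append(name)
        return FitResult(
            estimates=estimates,
            standard_errors=serrs,
            varcomps=varcomps,
            loglik=float(ll),
            converged=bool(res_ok and inner_ok and not separation),
            singular=singular,
            separation=separation,
            non_estimable=tuple(non_est),
            n_obs=self.n,
            n_groups={t.name: t.n_groups for t in self.terms},
            theta=theta,
            spec=self.spec,
            _model=self,
        )

    def _wald_se(self, theta, beta, Hxx, Hxu, Huu_pen, *, exact):
        """Wald standard errors from the observed information over beta.

        ``exact`` differentiates the Laplace objective numerically (the
        random-effect modes re-located at every evaluation); the fallback
        uses the cheaper profiled-information formula.
        """
        if exact:
            p = self.p
            step = 1e-4 * np.maximum(1.0, np.abs(beta))

            def f(b):
                ll, *_ = self.laplace_loglik(theta, b, warm=True)
                return ll

            try:
                self._warm = None
                H = np.empty((p, p))
                f0 = f(beta)
                for i in range(p):
                    for j in range(i, p):
                        bi, bj = np.zeros(p), np.zeros(p)
                        bi[i], bj[j] = step[i], step[j]
                        fpp = f(beta + bi + bj)
                        fpm = f(beta + bi - bj)
                        fmp = f(beta - bi + bj)
                        fmm = f(beta - bi - bj)
                        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                            4.0 * step[i] * step[j])
                cov = np.linalg.inv(-H)
                d = np.diag(cov)
                if np.all(np.isfinite(d)) and np.all(d > 0):
                    return np.sqrt(d)
            except np.linalg.LinAlgError:
                pass
        try:
            Hinv_xu = np.linalg.solve(Huu_pen, Hxu.T)
            cov = np.linalg.inv(Hxx - Hxu @ Hinv_xu)
            return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            return np.full(self.p, np.nan)

    def _degenerate_result(self) -> FitResult:
        nan = float("nan")
        return FitResult(
            estimates={k: nan for k in self.fixed_names},
            standard_errors={k: nan for k in self.fixed_names},
            varcomps={t.name: np.full((t.q, t.q), nan) for t in self.terms},
            loglik=nan,
            converged=False,
            singular=False,
            separation=True,
            non_estimable=tuple(self.fixed_names),
            n_obs=self.n,
            n_groups={t.name: t.n_groups for t in self.terms},
            theta=self.theta_init(),
            spec=self.spec,
            _model=self,
        )

    # -- simulation (for parametric bootstrap / recovery tests) ----------

    def simulate(self, rng: np.random.Generator, beta=None, theta=None,
                 fit: FitResult | None = None) -> np.ndarray:
        if fit is not None:
            beta = np.array([fit.estimates[k] for k in self.fixed_names])
            theta = fit.theta
        beta = np.asarray(beta, dtype=float)
        theta = np.asarray(theta, dtype=float)
        u = rng.standard_normal(self.q_total)
        meffs = self._effective_designs(theta)
        eta = self.X @ beta
        for cols, m in zip(self._cols, meffs):
            eta = eta + m * u[cols]
        return rng.binomial(self.ntrials.astype(np.int64),
                            special.expit(eta)).astype(float)


# ---------------------------------------------------------------------------
# module-level convenience API


def fit_logistic_mixed(spec: ModelSpec, table: pd.DataFrame, *,
                       theta0=None, fast=False) -> FitResult:
    """Fit a binomial-logit mixed model by Laplace-approximate ML.

    Crossed random factors are supported; standard errors are Wald errors
    from the observed information with the random effects profiled out.
    Non-convergence or separation is flagged on the result, never raised.
    """
    model = MixedLogitModel(spec, table)
    return model.fit(theta0=theta0, fast=fast)


def refit(fit: FitResult, y: np.ndarray, *, fast=True) -> FitResult:
    """Refit the same design against a replacement response vector."""
    model: MixedLogitModel = fit._model
    return model.fit(y=np.asarray(y, dtype=float), theta0=fit.theta,
                     fast=fast)


def simulate_response(fit: FitResult, rng: np.random.Generator) -> np.ndarray:
    """Draw one response vector from the fitted model (new random effects)."""
    return fit._model.simulate(rng, fit=fit)


def wald_test(fit: FitResult, term: str, reference_value: float = 0.0
              ) -> TestResult:
    """Two-tailed Wald z-test of one fixed term against a reference value."""
    if term not in fit.estimates:
        raise NonEstimableError(f"term {term!r} not in the fitted model")
    if term in fit.non_estimable:
        raise NonEstimableError(f"term {term!r} is not estimable")
    est = fit.estimates[term]
    se = fit.standard_errors[term]
    if not (se and se > 0 and math.isfinite(se)):
        raise NonEstimableError(f"term {term!r} has no finite standard error")
    z = (est - reference_value) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), df=None, p_value=float(p),
                      method="wald-z")


def likelihood_ratio_test(fit_full: FitResult, fit_reduced: FitResult,
                          *, tol: float = 1e-3) -> TestResult:
    """Chi-square LRT of nested fits (df = difference in fixed terms)."""
    df = fit_full.n_fixed - fit_reduced.n_fixed
    if df <= 0:
        raise ValueError("full model must have more fixed terms than reduced")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("LRT requires both fits to use the same rows")
    delta = fit_full.loglik - fit_reduced.loglik
    if delta < -tol:
        # optimizer failure on the full model: retry from the reduced optimum
        model: MixedLogitModel = fit_full._model
        retry = model.fit(theta0=fit_full.theta)
        if retry.loglik > fit_full.loglik:
            fit_full = retry
            delta = fit_full.loglik - fit_reduced.loglik
        if delta < -tol:
            raise RuntimeError(
                "full-model log-likelihood below the reduced model's "
                f"({delta:.4g}); the optimizer failed"
            )
    statistic = max(2.0 * delta, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return TestResult(statistic=float(statistic), df=df, p_value=p,
                      method="lrt")
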