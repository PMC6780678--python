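"""Random-intercept linear mixed model via profiled REML.

Model: y_ij = x_ij' beta + b_i + e_ij with b_i ~ N(0, sigma_b^2) and
e_ij ~ N(0, sigma^2), independent.  Writing lambda = sigma_b^2 / sigma^2,
the marginal covariance of subject i's block is sigma^2 (I + lambda J)
with J the all-ones matrix, whose inverse has the rank-one form
(I + lambda J)^-1 = I - (lambda / (1 + lambda n_i)) J.  This reduces the
GLS sufficient statistics to O(n) per subject and the restricted
likelihood to a one-dimensional profile over lambda, maximized by bounded
scalar search in log-lambda with an explicit evaluation at the lambda = 0
boundary.

A deliberately structure-free oracle fitter (`fit_oracle`) maximizes the
same restricted likelihood over (sigma_b^2, sigma^2) using the explicit
n x n marginal covariance; it exists so the fast path can be tested
against an independent computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .errors import EstimabilityError

logger = logging.getLogger(__name__)

_LAM_LO, _LAM_HI = 1e-8, 1e4


@dataclass
class LMMSpec:
    """Response, design matrix and subject grouping for one model fit."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.groups = np.asarray(self.groups)
        n, p = self.X.shape
        if self.y.shape != (n,) or self.groups.shape != (n,):
            raise ValueError("y, X and groups have inconsistent shapes")
        if len(self.columns) != p:
            raise ValueError("column names do not match design width")


@dataclass
class LMMFit:
    """A fitted random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    columns: list[str]
    cov_beta: np.ndarray
    sigma2_resid: float
    sigma2_subject: float
    lam: float
    reml_criterion: float
    n_obs: int
    n_subjects: int
    converged: bool
    method: str = "reml"

    def coef(self, term: str) -> float:
        return float(self.beta[self.columns.index(term)])


@dataclass
class WaldResult:
    beta: float
    se: float
    z: float
    ci95: tuple[float, float]
    p: float


# ---------------------------------------------------------------------------
# sufficient statistics and the profiled criterion
# ---------------------------------------------------------------------------

def _suffstats(spec: LMMSpec) -> dict:
    codes, _ = pd.factorize(spec.groups)
    order = np.argsort(codes, kind="stable")
    Xs, ys, cs = spec.X[order], spec.y[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cs) != 0])
    n_i = np.diff(np.r_[starts, len(cs)]).astype(float)
    return {
        "XtX": spec.X.T @ spec.X,
        "Xty": spec.X.T @ spec.y,
        "yty": float(spec.y @ spec.y),
        "G": np.add.reduceat(Xs, starts, axis=0),
        "gy": np.add.reduceat(ys, starts),
        "n_i": n_i,
        "n": len(spec.y),
        "p": spec.X.shape[1],
    }


def _criterion_at(st: dict, lam: float, reml: bool) -> tuple[float, dict]:
    """Profiled restricted (or marginal) log-likelihood at fixed lambda."""
    n, p, n_i = st["n"], st["p"], st["n_i"]
    w = lam / (1.0 + lam * n_i)
    A = st["XtX"] - (st["G"] * w[:, None]).T @ st["G"]
    b = st["Xty"] - st["G"].T @ (w * st["gy"])
    q = st["yty"] - float(w @ st["gy"] ** 2)
    beta = np.linalg.solve(A, b)
    rss = max(q - float(beta @ b), 1e-300)
    dof = (n - p) if reml else n
    sigma2 = rss / dof
    ldV = float(np.sum(np.log1p(lam * n_i)))
    ll = -0.5 * (dof * (np.log(2 * np.pi * sigma2) + 1.0) + ldV)
    if reml:
        ll -= 0.5 * float(np.linalg.slogdet(A)[1])
    return ll, {"beta": beta, "A": A, "sigma2": sigma2}


def profiled_criterion(spec: LMMSpec, lam: float, reml: bool = True) -> float:
    """Profiled REML (or ML) criterion at a given variance ratio lambda."""
    return _criterion_at(_suffstats(spec), lam, reml)[0]


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [columns[j] for j in piv[diag <= tol]] + [
            columns[j] for j in piv[len(diag):]
        ]
        raise EstimabilityError(f"design matrix is rank deficient; aliased column(s): {aliased}")


def fit_random_intercept(spec: LMMSpec, reml: bool = True) -> LMMFit:
    """Fit the random-intercept model by profiled REML (default) or ML.

    The variance ratio lambda = sigma_b^2/sigma^2 is profiled out: the
    criterion is maximized over log-lambda on [1e-8, 1e4] by bounded
    scalar search, with the lambda = 0 boundary evaluated explicitly.
    Standard errors are model-based, from the GLS information matrix.
    """
    _check_rank(spec.X, spec.columns)
    st = _suffstats(spec)
    n, p = st["n"], st["p"]
    if n <= p:
        raise EstimabilityError(f"need n_obs > n_params, got n={n}, p={p}")

    converged = True
    if np.all(st["n_i"] == 1):
        logger.warning("all subjects are singletons; lambda fixed at 0")
        lam_hat = 0.0
    else:
        def neg(t: float) -> float:
            return -_criterion_at(st, np.exp(t), reml)[0]

        res = scipy.optimize.minimize_scalar(
            neg,
            bounds=(np.log(_LAM_LO), np.log(_LAM_HI)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(res.success)
        candidates = [0.0, float(np.exp(res.x)), _LAM_LO, _LAM_HI]
        lls = [_criterion_at(st, c, reml)[0] for c in candidates]
        lam_hat = candidates[int(np.argmax(lls))]

    ll, parts = _criterion_at(st, lam_hat, reml)
    cov_beta = parts["sigma2"] * np.linalg.inv(parts["A"])
    se = np.sqrt(np.diag(cov_beta))
    return LMMFit(
        beta=parts["beta"],
        se=se,
        columns=list(spec.columns),
        cov_beta=cov_beta,
        sigma2_resid=float(parts["sigma2"]),
        sigma2_subject=float(lam_hat * parts["sigma2"]),
        lam=float(lam_hat),
        reml_criterion=float(ll),
        n_obs=int(n),
        n_subjects=int(len(st["n_i"])),
        converged=converged,
        method="reml" if reml else "ml",
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _full_restricted_ll(
    y: np.ndarray, X: np.ndarray, ZZt: np.ndarray, sb2: float, s2: float, reml: bool
) -> float:
    n, p = X.shape
    V = s2 * np.eye(n) + sb2 * ZZt
    try:
        cho = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError:
        return -np.inf
    ldV = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Vi_X = scipy.linalg.cho_solve(cho, X)
    Vi_y = scipy.linalg.cho_solve(cho, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ scipy.linalg.cho_solve(cho, r))
    if reml:
        ld2 = float(np.linalg.slogdet(XtViX)[1])
        return -0.5 * (ldV + ld2 + quad + (n - p) * np.log(2 * np.pi))
    return -0.5 * (ldV + quad + n * np.log(2 * np.pi))


def fit_oracle(spec: LMMSpec, reml: bool = True) -> LMMFit:
    """Maximize the restricted likelihood over (sigma_b^2, sigma^2) by
    generic 2-D numerical optimization on the explicit n x n covariance.

    Intended for small problems (n <= ~200) as an independent comparison
    arm; exploits no block structure.  Deterministic: fixed multistarts,
    no internal randomness.
    """
    _check_rank(spec.X, spec.columns)
    y, X = spec.y, spec.X
    n, p = X.shape
    if n > 200:
        raise ValueError("fit_oracle is restricted to n <= 200 observations")
    codes, _ = pd.factorize(spec.groups)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    ZZt = Z @ Z.T

    vy = float(np.var(y)) or 1.0

    def neg(theta: np.ndarray) -> float:
        sb2, s2 = theta
        if s2 <= 0 or sb2 < 0:
            return np.inf
        return -_full_restricted_ll(y, X, ZZt, sb2, s2, reml)

    starts = [
        (0.3 * vy, 0.7 * vy),
        (1e-4 * vy, vy),
        (vy, 0.3 * vy),
        (0.05 * vy, 0.5 * vy),
    ]
    best = None
    for s0 in starts:
        res = scipy.optimize.minimize(
            neg,
            x0=np.array(s0),
            method="L-BFGS-B",
            bounds=[(0.0, None), (1e-12 * vy, None)],
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish with a derivative-free pass for tight agreement
    polish = scipy.optimize.minimize(
        neg,
        x0=best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-13, "maxiter": 4000},
    )
    if polish.fun <= best.fun:
        best = polish
    if not np.isfinite(best.fun):
        raise EstimabilityError("oracle optimizer failed to converge")

    sb2, s2 = float(max(best.x[0], 0.0)), float(best.x[1])
    lam = sb2 / s2
    ll = -best.fun

    V = s2 * np.eye(n) + sb2 * ZZt
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ Vi @ y)
    return LMMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        columns=list(spec.columns),
        cov_beta=cov_beta,
        sigma2_resid=s2,
        sigma2_subject=sb2,
        lam=lam,
        reml_criterion=float(ll),
        n_obs=int(n),
        n_subjects=int(Z.shape[1]),
        converged=True,
        method="reml" if reml else "ml",
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def wald_test(fit: LMMFit, term: str, use_t: bool = False) -> WaldResult:
    """Wald test for one fixed-effect term.

    Default reference distribution is standard normal (z); ``use_t=True``
    switches to a t reference with n_obs - p residual degrees of freedom.
    The 95% CI is beta +/- z_{0.975} * se.
    """
    if term not in fit.columns:
        raise KeyError(f"term {term!r} not in fitted columns {fit.columns}")
    j = fit.columns.index(term)
    beta, se = float(fit.beta[j]), float(fit.se[j])
    if se == 0 or not np.isfinite(se):
        raise EstimabilityError(f"term {term!r} has degenerate standard error {se!r}")
    z = beta / se
    if use_t:
        df = fit.n_obs - len(fit.columns)
        p = 2.0 * scipy.stats.t.sf(abs(z), df)
        crit = scipy.stats.t.ppf(0.975, df)
    else:
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        crit = scipy.stats.norm.ppf(0.975)
    return WaldResult(beta=beta, se=se, z=z, ci95=(beta - crit * se, beta + crit * se), p=float(p))
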