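"""Negative-binomial GLM engine shared by calibration and DE.

Mean model: log E[y] = X beta + offset, NB2 variance mu + alpha*mu^2.
Coefficients are fit by iteratively reweighted least squares (IRLS) at a
fixed dispersion; the dispersion alpha is estimated by profile maximum
likelihood, alternating with the coefficient update. When the profile
likelihood is maximized at alpha -> 0 the fit falls back to Poisson
(alpha = 0).

These are small dense problems (tens of species per cell, hundreds of cells
per gene) so plain numpy linear algebra is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "GLMFit",
    "fit_nb_glm",
    "nb_loglik",
    "nb_deviance",
    "natural_spline_basis",
]

_ALPHA_MIN = 1e-8
_ALPHA_MAX = 1e3
_POISSON_ALPHA_CUT = 1e-6


@dataclass
class GLMFit:
    """Result of one NB (or Poisson) GLM fit."""

    beta: np.ndarray
    alpha: float  # NB2 dispersion; 0 means Poisson
    llf: float
    mu: np.ndarray
    converged: bool
    n_iter: int

    def deviance(self, y: np.ndarray) -> float:
        return nb_deviance(y, self.mu, self.alpha)


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (Poisson when alpha == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1)
            + y * np.log(alpha * mu)
            - (y + inv) * np.log1p(alpha * mu)
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 deviance 2*[ll(saturated) - ll(mu)] at fixed alpha."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        if alpha <= 0:
            term = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        else:
            ylog = np.where(y > 0, y * np.log(y / mu), 0.0)
            term = ylog - (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return float(2.0 * np.sum(term))


def _irls(y, X, offset, alpha, beta0=None, max_iter=100, tol=1e-8):
    """IRLS for log-link NB2/Poisson at fixed alpha."""
    n, p = X.shape
    if beta0 is None:
        # initialize from log of shifted response regressed on X
        z0 = np.log(y + 0.5) - offset
        beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    else:
        beta = beta0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + offset
        eta = np.clip(eta, -500, 500)
        mu = np.exp(eta)
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + alpha * mu)  # working weights for log link, NB2
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)
        delta = np.max(np.abs(beta_new - beta) / (np.abs(beta) + 1e-8))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -500, 500)
    mu = np.maximum(np.exp(eta), 1e-300)
    return beta, mu, converged, it


def _profile_alpha(y, mu, bracket_lo=_ALPHA_MIN, bracket_hi=_ALPHA_MAX):
    """ML estimate of alpha with the mean held fixed."""

    def negll(log_a):
        return -nb_loglik(y, mu, np.exp(log_a))

    res = optimize.minimize_scalar(
        negll,
        bounds=(np.log(bracket_lo), np.log(bracket_hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    a = float(np.exp(res.x))
    # boundary check: Poisson beats any positive alpha
    if nb_loglik(y, mu, 0.0) >= -res.fun:
        return 0.0
    return a


def fit_nb_glm(
    y,
    X,
    offset=None,
    alpha: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    n_alpha_rounds: int = 4,
) -> GLMFit:
    """Fit log E[y] = X beta + offset with NB2 errors.

    If ``alpha`` is given it is held fixed; otherwise it is profiled by ML,
    alternating coefficient and dispersion updates. Poisson fallback when
    the likelihood is maximized at alpha -> 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("design rows must match response length")
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    if alpha is not None:
        beta, mu, conv, it = _irls(y, X, offset, alpha, max_iter=max_iter, tol=tol)
        return GLMFit(beta, float(alpha), nb_loglik(y, mu, alpha), mu, conv, it)

    # alternate: Poisson start, then profile alpha <-> refit beta
    a = 0.0
    beta, mu, conv, it = _irls(y, X, offset, 0.0, max_iter=max_iter, tol=tol)
    total_it = it
    for _ in range(n_alpha_rounds):
        a_new = _profile_alpha(y, mu)
        if a_new <= _POISSON_ALPHA_CUT:
            a_new = 0.0
        beta, mu, conv, it = _irls(
            y, X, offset, a_new, beta0=beta, max_iter=max_iter, tol=tol
        )
        total_it += it
        if abs(a_new - a) <= 1e-6 * (a + 1e-6):
            a = a_new
            break
        a = a_new
    return GLMFit(beta, float(a), nb_loglik(y, mu, a), mu, conv, total_it)


def natural_spline_basis(
    x,
    df: int = 3,
    knots: np.ndarray | None = None,
    boundary_knots: tuple[float, float] | None = None,
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), df columns.

    Truncated-power construction: with knots xi_1 < ... < xi_K
    (K = df + 1: two boundary knots at the data range, interior knots at
    quantiles), the basis is {x, N_1(x), ..., N_{K-2}(x)} with

        N_k(x) = d_k(x) - d_{K-1}(x),
        d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k),

    which is linear beyond the boundary knots and spans the same space as
    the usual B-spline natural basis.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    if knots is None:
        if boundary_knots is None:
            lo, hi = float(np.min(x)), float(np.max(x))
        else:
            lo, hi = boundary_knots
        if hi <= lo:
            raise ValueError("x must span a positive range")
        n_interior = df - 1
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        knots = np.concatenate([[lo], interior, [hi]])
    knots = np.asarray(knots, dtype=float)
    K = knots.size
    xiK = knots[-1]
    xiKm1 = knots[-2]

    def d(k):
        return (
            np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - xiK, 0) ** 3
        ) / (xiK - knots[k])

    dKm1 = (np.maximum(x - xiKm1, 0) ** 3 - np.maximum(x - xiK, 0) ** 3) / (
        xiK - xiKm1
    )
    cols = [x] + [d(k) - dKm1 for k in range(K - 2)]
    return np.column_stack(cols)


class NaturalSpline:
    """Natural cubic spline basis with knots frozen at construction.

    Knots (boundary at the training range, interior at quantiles) and the
    per-column scale are fixed from the training ``x`` so the basis can be
    evaluated consistently on new points (e.g. a prediction grid).
    """

    def __init__(self, x, df: int = 3):
        x = np.asarray(x, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError("x must span a positive range")
        self.df = df
        if df == 1:
            self.knots = np.array([lo, hi])
        else:
            qs = np.linspace(0, 1, df + 1)[1:-1]
            interior = np.quantile(x, qs)
            self.knots = np.concatenate([[lo], interior, [hi]])
        raw = natural_spline_basis(x, df=df, knots=self.knots if df > 1 else None)
        self.scale = np.maximum(np.abs(raw).max(axis=0), 1e-12)

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.df == 1:
            return (x[:, None]) / self.scale
        return natural_spline_basis(x, df=self.df, knots=self.knots) / self.scale
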