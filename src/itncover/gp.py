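"""Exact space-time Gaussian-process regression for deviation surfaces.

The model for a transformed deviation metric y at pixel s and month t is

    y(s, t) = x(s, t)' beta + f(s, t) + e,    e ~ N(0, nugget)

where f is a zero-mean Gaussian field with separable covariance

    Cov[f(s,t), f(s',t')] = sigma^2 * matern32(|s - s'| / rho) * phi^|t - t'|

— a Matern(nu = 3/2) spatial kernel with range rho (grid units) times a
first-order autoregressive month-to-month component with coefficient phi.
Hyperparameters are set by maximising the Gaussian marginal likelihood with
the fixed effects profiled out (GLS). Everything is an exact dense solve:
at desk scale (a few thousand observations) no sparse/mesh approximation is
needed, and the dense solution is the reference such approximations target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

__all__ = ["GPHyperparams", "matern32", "spacetime_covariance", "GPModel", "fit_gp"]


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel hyperparameters. ``nu`` is fixed at 3/2 by construction."""

    sigma2: float = 1.0     # sill variance
    rho: float = 5.0        # spatial range, grid distance units
    phi: float = 0.5        # AR1 month-to-month coefficient
    nugget: float = 0.1     # iid observation variance

    def __post_init__(self) -> None:
        if self.sigma2 < 0 or self.nugget < 0:
            raise ValueError("sigma2 and nugget must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not (-1.0 < self.phi < 1.0):
            raise ValueError("phi must be in (-1, 1)")


def matern32(d, hyper: GPHyperparams):
    """Matern covariance with smoothness 3/2:
    ``sigma^2 (1 + sqrt(3) d / rho) exp(-sqrt(3) d / rho)``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    a = np.sqrt(3.0) * d / hyper.rho
    return hyper.sigma2 * (1.0 + a) * np.exp(-a)


def spacetime_covariance(coords_a, times_a, coords_b, times_b,
                         hyper: GPHyperparams, *, nugget_diag: bool = False):
    """Dense covariance matrix between two sets of (pixel, month) points.

    ``nugget_diag`` adds the nugget on exact point coincidences (use for the
    training covariance only).
    """
    d = cdist(np.asarray(coords_a, float), np.asarray(coords_b, float))
    dt = np.abs(np.subtract.outer(np.asarray(times_a, float), np.asarray(times_b, float)))
    K = matern32(d, hyper) * hyper.phi ** dt
    if nugget_diag:
        K = K + hyper.nugget * ((d == 0) & (dt == 0))
    return K


class GPModel:
    """A fitted GP regression: hyperparameters, GLS fixed effects, and the
    factorised training covariance needed for prediction."""

    def __init__(self, coords, times, y, X, hyper: GPHyperparams):
        self.coords = np.asarray(coords, float)
        self.times = np.asarray(times, float)
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.hyper = hyper
        self._factorise()

    def _factorise(self) -> None:
        K = spacetime_covariance(self.coords, self.times, self.coords, self.times,
                                 self.hyper, nugget_diag=True)
        self._cho = _safe_cholesky(K)
        Kinv_X = linalg.cho_solve(self._cho, self.X)
        Kinv_y = linalg.cho_solve(self._cho, self.y)
        XtKiX = self.X.T @ Kinv_X
        self.beta = linalg.solve(XtKiX, self.X.T @ Kinv_y, assume_a="pos")
        self.resid = self.y - self.X @ self.beta
        self._Kinv_resid = linalg.cho_solve(self._cho, self.resid)

    def log_marginal_likelihood(self) -> float:
        n = self.y.size
        logdet = 2.0 * np.sum(np.log(np.diag(self._cho[0])))
        return float(-0.5 * (self.resid @ self._Kinv_resid) - 0.5 * logdet
                     - 0.5 * n * np.log(2.0 * np.pi))

    def predict(self, coords_new, times_new, X_new,
                n_draws: int = 0, rng: np.random.Generator | None = None):
        """Posterior mean (and optional joint draws) at new (pixel, month) points.

        Returns ``mean`` or ``(mean, draws)`` with draws of shape
        ``(n_draws, n_points)``. Fixed-effect coefficients are treated as
        known at their GLS estimates.
        """
        Ks = spacetime_covariance(coords_new, times_new, self.coords, self.times, self.hyper)
        mean = np.asarray(X_new, float) @ self.beta + Ks @ self._Kinv_resid
        if n_draws == 0:
            return mean
        rng = rng or np.random.default_rng()
        Kss = spacetime_covariance(coords_new, times_new, coords_new, times_new, self.hyper)
        V = Kss - Ks @ linalg.cho_solve(self._cho, Ks.T)
        # symmetrise and factorise the predictive covariance
        V = 0.5 * (V + V.T)
        L = np.tril(_safe_cholesky(V)[0])
        z = rng.standard_normal((n_draws, mean.size))
        return mean, mean[None, :] + z @ L.T


def _safe_cholesky(K: np.ndarray, max_tries: int = 6):
    """cho_factor (lower) with escalating diagonal jitter."""
    jitter = 0.0
    base = max(np.mean(np.diag(K)), 1e-12)
    for i in range(max_tries):
        try:
            return linalg.cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = base * 10.0 ** (i - 10)
    raise linalg.LinAlgError(
        f"covariance not positive definite after jitter up to {jitter:.1e}"
    )


def fit_gp(coords, times, y, X=None, hyper0: GPHyperparams | None = None,
           *, estimate_phi: bool = True) -> GPModel:
    """Fit the space-time GP by maximum marginal likelihood.

    Parameters
    ----------
    coords : (n, 2) pixel coordinates in grid units.
    times : (n,) month indices.
    y : (n,) transformed responses.
    X : (n, p) fixed-effect design; defaults to an intercept column.
    hyper0 : starting hyperparameters.
    estimate_phi : optimise the AR1 coefficient (fix it at ``hyper0.phi``
        when all observations share one month).
    """
    coords = np.asarray(coords, float)
    times = np.asarray(times, float)
    y = np.asarray(y, float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if X is None:
        X = np.ones((n, 1))
    key = np.round(np.column_stack([coords, times]), 9)
    if np.unique(key, axis=0).shape[0] != n:
        raise ValueError("duplicated space-time points; jitter coordinates first")
    hyper0 = hyper0 or GPHyperparams(sigma2=float(np.var(y)) or 1.0,
                                     rho=max(np.ptp(coords) / 4.0, 1.0),
                                     phi=0.5,
                                     nugget=0.1 * (float(np.var(y)) or 1.0))

    def unpack(theta) -> GPHyperparams:
        s2, rho, ng = np.exp(theta[:3])
        phi = np.tanh(theta[3]) if estimate_phi else hyper0.phi
        return GPHyperparams(sigma2=s2, rho=rho, phi=phi, nugget=ng)

    def negloglik(theta):
        try:
            m = GPModel(coords, times, y, X, unpack(theta))
            return -m.log_marginal_likelihood()
        except (linalg.LinAlgError, ValueError):
            return 1e10

    theta0 = [np.log(hyper0.sigma2), np.log(hyper0.rho),
              np.log(max(hyper0.nugget, 1e-8)), np.arctanh(np.clip(hyper0.phi, -0.99, 0.99))]
    if not estimate_phi:
        theta0 = theta0[:3] + [0.0]
    res = optimize.minimize(negloglik, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    return GPModel(coords, times, y, X, unpack(res.x))
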