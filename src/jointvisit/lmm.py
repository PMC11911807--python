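"""Linear mixed model for the longitudinal marker.

The marker is modelled as

    Y_i(t) = X_i(t)' beta + Z_i(t)' b_i + eps_i(t),

with ``b_i ~ N(0, D)`` and ``eps_i(t) ~ N(0, sigma^2)``.  The module provides

* the *marginal* log-density of a subject's observed marker vector,
  ``Y_i ~ N(X_i beta, sigma^2 I + Z_i D Z_i')``,
* the posterior of the random effects given the marker only,
  ``b_i | Y_i ~ N(mu_i, C_i)`` with ``C_i^{-1} = D^{-1} + Z_i' Z_i / sigma^2``
  and ``mu_i = C_i Z_i' (Y_i - X_i beta) / sigma^2`` (the importance density
  of the pseudo-adaptive quadrature), and
* the latent "true" marker value ``m_i(t) = X_i(t)'beta + Z_i(t)'b_i`` and
  its time slope ``m_i'(t)``, which enter the visiting and event hazards.

All log-densities are computed through Cholesky solves, never through an
explicit inverse of the ``n_i x n_i`` marginal covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Tuple

import numpy as np
from scipy import linalg

__all__ = ["MarkerBasis", "LmmParams", "PosteriorRE", "cd4_preset_basis",
           "marker_marginal_loglik", "posterior_re", "true_value_and_slope"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MarkerBasis:
    """Design-matrix generators for the fixed and random parts.

    ``fixed`` and ``random`` map a vector of times (and a dict of subject
    covariates) to design matrices with one row per time.  Analytic time
    derivatives may be supplied; otherwise central differences with step
    ``h = 1e-5 * max(1, |t|)`` are used for the slope.
    """

    fixed: Callable[[np.ndarray, Mapping], np.ndarray]
    random: Callable[[np.ndarray, Mapping], np.ndarray]
    fixed_deriv: Optional[Callable[[np.ndarray, Mapping], np.ndarray]] = None
    random_deriv: Optional[Callable[[np.ndarray, Mapping], np.ndarray]] = None
    t_max: float = np.inf

    def X(self, t, covariates: Mapping | None = None) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t)
        return np.atleast_2d(self.fixed(t, covariates or {}))

    def Z(self, t, covariates: Mapping | None = None) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t)
        return np.atleast_2d(self.random(t, covariates or {}))

    def dX(self, t, covariates: Mapping | None = None) -> np.ndarray:
        if self.fixed_deriv is not None:
            t = np.atleast_1d(np.asarray(t, dtype=float))
            return np.atleast_2d(self.fixed_deriv(t, covariates or {}))
        return self._central_diff(self.fixed, t, covariates or {})

    def dZ(self, t, covariates: Mapping | None = None) -> np.ndarray:
        if self.random_deriv is not None:
            t = np.atleast_1d(np.asarray(t, dtype=float))
            return np.atleast_2d(self.random_deriv(t, covariates or {}))
        return self._central_diff(self.random, t, covariates or {})

    def _central_diff(self, f, t, cov) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        h = 1e-5 * np.maximum(1.0, np.abs(t))
        return (np.atleast_2d(f(t + h, cov)) - np.atleast_2d(f(t - h, cov))) / (2.0 * h[:, None])

    def _check_domain(self, t: np.ndarray) -> None:
        if np.any(t < -1e-12) or np.any(t > self.t_max + 1e-12):
            raise ValueError(f"time outside basis domain [0, {self.t_max}]")


def cd4_preset_basis(t_max: float = np.inf) -> MarkerBasis:
    """The {1, log(t+1), (t/10)^3} basis used for sqrt(CD4)-style trajectories.

    Both the fixed- and random-effect designs use the same three functions
    of time since baseline (years), with analytic derivatives
    {0, 1/(t+1), 3 t^2 / 1000}.
    """

    def _b(t, cov):
        t = np.asarray(t, dtype=float)
        return np.column_stack([np.ones_like(t), np.log(t + 1.0), (t / 10.0) ** 3])

    def _db(t, cov):
        t = np.asarray(t, dtype=float)
        return np.column_stack([np.zeros_like(t), 1.0 / (t + 1.0), 3.0 * t**2 / 1000.0])

    return MarkerBasis(fixed=_b, random=_b, fixed_deriv=_db, random_deriv=_db, t_max=t_max)


@dataclass
class LmmParams:
    """Marker-model parameter block ``theta_l = (beta, D, sigma^2)``."""

    beta: np.ndarray
    D: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        try:
            linalg.cholesky(self.D, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("random-effects covariance D is not positive definite") from exc

    @property
    def q(self) -> int:
        return self.D.shape[0]


@dataclass
class PosteriorRE:
    """Moments of ``b_i | Y_i`` used as importance density.

    ``B`` is an upper-triangular factor with ``C^{-1} = B' B`` (Cholesky of
    the posterior precision), so nodes are mapped through ``B^{-1}``.
    """

    mu: np.ndarray
    C: np.ndarray
    B: np.ndarray

    def B_inv(self) -> np.ndarray:
        return linalg.solve_triangular(self.B, np.eye(self.B.shape[0]), lower=False)

    def C_factor(self) -> np.ndarray:
        """Lower Cholesky factor of C (for sampling from N(mu, C))."""
        return linalg.cholesky(self.C, lower=True)


def _marginal_chol(Z: np.ndarray, theta: LmmParams) -> np.ndarray:
    n = Z.shape[0]
    V = theta.sigma2 * np.eye(n) + Z @ theta.D @ Z.T
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("marginal marker covariance not positive definite") from exc


def marker_marginal_loglik(Y: np.ndarray, X: np.ndarray, Z: np.ndarray, theta: LmmParams) -> float:
    """Log of ``N(Y; X beta, sigma^2 I + Z D Z')`` for one subject.

    ``X``/``Z`` are the subject's stacked design matrices at the visit
    times.  Computed via the Cholesky factor of the marginal covariance.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(X)
    Z = np.atleast_2d(Z)
    n = Y.shape[0]
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("design matrices and marker vector have mismatched lengths")
    if X.shape[1] != theta.beta.shape[0] or Z.shape[1] != theta.q:
        raise ValueError("design matrices and parameters have mismatched widths")
    L = _marginal_chol(Z, theta)
    r = Y - X @ theta.beta
    u = linalg.solve_triangular(L, r, lower=True)
    return float(-0.5 * n * _LOG2PI - np.sum(np.log(np.diag(L))) - 0.5 * u @ u)


def posterior_re(Y: np.ndarray, X: np.ndarray, Z: np.ndarray, theta: LmmParams) -> PosteriorRE:
    """Posterior ``b_i | Y_i ~ N(mu_i, C_i)`` from the marker model alone.

    ``C_i^{-1} = D^{-1} + Z'Z / sigma^2`` and
    ``mu_i = C_i Z' (Y - X beta) / sigma^2``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(X)
    Z = np.atleast_2d(Z)
    try:
        cf = linalg.cho_factor(theta.D, lower=True)
        D_inv = linalg.cho_solve(cf, np.eye(theta.q))
    except linalg.LinAlgError as exc:
        raise ValueError("random-effects covariance D is singular") from exc
    prec = D_inv + Z.T @ Z / theta.sigma2
    prec = 0.5 * (prec + prec.T)
    B = linalg.cholesky(prec, lower=False)  # prec = B' B with B upper
    C = linalg.cho_solve((B.T, True), np.eye(prec.shape[0]))
    C = 0.5 * (C + C.T)
    mu = C @ (Z.T @ (Y - X @ theta.beta)) / theta.sigma2
    return PosteriorRE(mu=mu, C=C, B=B)


def true_value_and_slope(
    b: np.ndarray,
    basis: MarkerBasis,
    theta: LmmParams,
    t,
    covariates: Mapping | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Latent marker value ``m_i(t)`` and slope ``m_i'(t)`` for one subject.

    Vectorised over ``t``; scalars in, scalars out.
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    X = basis.X(t_arr, covariates)
    Z = basis.Z(t_arr, covariates)
    dX = basis.dX(t_arr, covariates)
    dZ = basis.dZ(t_arr, covariates)
    b = np.asarray(b, dtype=float)
    m = X @ theta.beta + Z @ b
    dm = dX @ theta.beta + dZ @ b
    if scalar:
        return float(m[0]), float(dm[0])
    return m, dm
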