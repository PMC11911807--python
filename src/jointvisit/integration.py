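"""Numerical integration machinery.

Two integration problems arise when evaluating the marginal likelihood of the
joint model:

1. one-dimensional integrals of hazard/intensity functions over inter-visit
   intervals, handled by a fixed (non-adaptive) 15-point Gauss--Kronrod rule
   per interval piece, and
2. the marginalisation of the conditional likelihood over the subject-level
   random effects ``b_i``, handled by pseudo-adaptive Gauss--Hermite
   quadrature (or quasi-Monte-Carlo sampling) that uses the posterior of the
   random effects given the *marker submodel only*, ``b_i | Y_i ~ N(mu_i,
   C_i)``, as importance density.

The same node weights produced during the marginalisation are reused to
assemble the score vector, so :func:`marginalize_re` returns them alongside
the log marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np
from scipy.stats import qmc

__all__ = [
    "QuadratureRule",
    "gauss_kronrod_15",
    "gk15_nodes",
    "marginalize_re",
]

# 15-point Gauss-Kronrod rule on [-1, 1] (symmetric; nodes listed for the
# positive half axis, mirrored below).
_GK15_NODES_POS = np.array(
    [
        0.991455371120812639206854697526329,
        0.949107912342758524526189684047851,
        0.864864423359769072789712788640926,
        0.741531185599394439863864773280788,
        0.586087235467691130294144838258730,
        0.405845151377397166906606412076961,
        0.207784955007898467600689403773245,
        0.000000000000000000000000000000000,
    ]
)
_GK15_WEIGHTS_POS = np.array(
    [
        0.022935322010529224963732008058970,
        0.063092092629978553290700663189204,
        0.104790010322250183839876322541518,
        0.140653259715525918745189590510238,
        0.169004726639267902826583426598550,
        0.190350578064785409913256402421014,
        0.204432940075298892414161999234649,
        0.209482141084727828012999174891714,
    ]
)

_GK15_X = np.concatenate([-_GK15_NODES_POS[:-1], _GK15_NODES_POS[::-1]])
_GK15_W = np.concatenate([_GK15_WEIGHTS_POS[:-1], _GK15_WEIGHTS_POS[::-1]])
# sort nodes increasingly for readability of downstream caches
_order = np.argsort(_GK15_X)
_GK15_X = _GK15_X[_order]
_GK15_W = _GK15_W[_order]


def gk15_nodes(a: float, b: float) -> Tuple[np.ndarray, np.ndarray]:
    """Nodes and weights of the 15-point Gauss-Kronrod rule mapped to [a, b].

    Returns ``(x, w)`` with ``sum(w * f(x))`` approximating the integral of
    ``f`` over ``[a, b]``.  Raises ``ValueError`` when ``a > b``.
    """
    if a > b:
        raise ValueError(f"invalid integration interval: a={a} > b={b}")
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    return mid + half * _GK15_X, half * _GK15_W


def gauss_kronrod_15(f: Callable[[np.ndarray], np.ndarray], a: float, b: float) -> float:
    """Fixed 15-node Gauss-Kronrod estimate of ``int_a^b f``.

    One panel only, no adaptivity: inter-visit pieces of the hazard
    integrands are short and smooth, so a single high-order panel per piece
    is both fast and accurate.  ``f`` must accept a vector of abscissae.
    """
    x, w = gk15_nodes(a, b)
    if a == b:
        return 0.0
    return float(np.dot(w, np.asarray(f(x), dtype=float)))


@dataclass
class QuadratureRule:
    """Configuration of the random-effects marginalisation.

    Parameters
    ----------
    kind:
        ``"GH"`` for tensor-product Gauss-Hermite or ``"QMC"`` for scrambled
        Sobol quasi-Monte-Carlo draws from the importance density.
    n_nodes:
        Gauss-Hermite nodes per random-effect dimension.
    n_draws:
        Number of QMC draws.
    seed:
        Seed for QMC scrambling (ignored for GH).
    prune:
        Tensor-product GH weights below this threshold are dropped.
    """

    kind: str = "GH"
    n_nodes: int = 7
    n_draws: int = 500
    seed: int = 0
    prune: float = 1e-10
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("GH", "QMC"):
            raise ValueError(f"unknown quadrature kind {self.kind!r}")

    def gh_grid(self, q: int) -> Tuple[np.ndarray, np.ndarray]:
        """Tensor-product standard GH abscissae ``(q, M)`` and weights ``(M,)``.

        Weights are the raw products of 1-d Gauss-Hermite weights (Gaussian
        weight function ``exp(-a'a)``); the ``pi^{-q/2}`` normaliser is
        applied by :func:`marginalize_re`.
        """
        key = ("gh", q)
        if key not in self._cache:
            a1, w1 = np.polynomial.hermite.hermgauss(self.n_nodes)
            grids = np.meshgrid(*([a1] * q), indexing="ij")
            nodes = np.stack([g.ravel() for g in grids])  # (q, n^q)
            wgrids = np.meshgrid(*([w1] * q), indexing="ij")
            weights = np.prod(np.stack([g.ravel() for g in wgrids]), axis=0)
            keep = weights > self.prune
            self._cache[key] = (nodes[:, keep], weights[keep])
        return self._cache[key]

    def qmc_std_normal(self, q: int) -> np.ndarray:
        """Scrambled-Sobol standard-normal draws, shape ``(q, n_draws)``."""
        key = ("qmc", q)
        if key not in self._cache:
            eng = qmc.Sobol(d=q, scramble=True, seed=self.seed)
            u = eng.random(self.n_draws)
            # keep strictly inside (0,1) for the normal ppf
            u = np.clip(u, 1e-12, 1 - 1e-12)
            from scipy.stats import norm

            self._cache[key] = norm.ppf(u).T
        return self._cache[key]


def marginalize_re(
    cond_loglik: Callable[[np.ndarray], np.ndarray],
    post,
    rule: QuadratureRule,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Marginalise a conditional log-likelihood over the random effects.

    ``cond_loglik`` maps a matrix of random-effect values ``b`` with shape
    ``(q, M)`` to the ``(M,)`` vector of conditional log-likelihood values
    ``log f(N, T, K | Y, b)``.  ``post`` is the marker-only posterior
    (:class:`jointvisit.lmm.PosteriorRE`) used as importance density.

    Returns ``(log_marginal, node_weights, b_nodes)`` where ``node_weights``
    are the nonnegative, normalised posterior weights
    ``f(b | Y, N, T, K) / f(b | Y)`` evaluated at the nodes -- exactly the
    weights required to turn complete-data scores into the observed-data
    score -- and ``b_nodes`` is the ``(q, M)`` matrix of node locations.
    """
    mu = np.asarray(post.mu, dtype=float)
    q = mu.shape[0]
    if rule.kind == "GH":
        a, w = rule.gh_grid(q)
        # b = mu + sqrt(2) * B^{-1} a  with  C^{-1} = B' B
        b = mu[:, None] + np.sqrt(2.0) * post.B_inv() @ a
        logw = np.log(w) - 0.5 * q * np.log(np.pi)
    else:
        z = rule.qmc_std_normal(q)
        b = mu[:, None] + post.C_factor() @ z
        logw = np.full(b.shape[1], -np.log(b.shape[1]))

    vals = np.asarray(cond_loglik(b), dtype=float)
    terms = vals + logw
    m = np.max(terms)
    if not np.isfinite(m):
        return -np.inf, np.zeros(b.shape[1]), b
    ex = np.exp(terms - m)
    s = ex.sum()
    log_marg = float(m + np.log(s))
    weights = ex / s
    return log_marg, weights, b
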