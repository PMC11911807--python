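"""Marginal maximum-likelihood estimation of the joint model.

The observed-data likelihood of one subject factorises as

    f(Y_i; theta_l) * Integral f(N_i | Y_i, b) f(T_i, K_i | Y_i, b)
                               f(b | Y_i; theta_l) db,

where the first factor is the marginal Gaussian law of the marker vector and
the integral is taken against the marker-only posterior of the random
effects, evaluated by pseudo-adaptive Gauss-Hermite quadrature (or QMC).

The score is assembled from the same quadrature nodes: with node weights
``w_m = f(b_m | Y, N, T, K) / f(b_m | Y)`` returned by the marginaliser, the
observed-data score equals the weighted average of the complete-data score

    A(theta, b) = d/dtheta log{ f(Y|b) f(N|Y,b) f(T,K|Y,b) f(b) },

computed analytically for every parameter block, with the chain rule through
the unconstrained parametrisation: ``D`` via the matrix logarithm
(vech of ``log D``), ``sigma^2`` and the frailty variance ``eta`` via logs.

BFGS is used for maximisation; standard errors come from the inverse of the
Hessian of the negative log-likelihood at the optimum, obtained by central
finite differences of the analytic score on the packed scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, optimize
from scipy.special import digamma, gammaln

from .hazards import (CauseModel, CauseParams, VisitParams, VisitProcessModel,
                      _Prepared, _EXP_CLIP)
from .integration import QuadratureRule, marginalize_re
from .lmm import (LmmParams, MarkerBasis, PosteriorRE, marker_marginal_loglik,
                  posterior_re)

logger = logging.getLogger("jointvisit")

__all__ = ["JointParams", "JointModel", "FitResult", "derived_mean_marker",
            "vech", "unvech", "pack_cov", "unpack_cov"]


# ---------------------------------------------------------------------------
# covariance transforms
# ---------------------------------------------------------------------------

def vech(M: np.ndarray) -> np.ndarray:
    """Stack the lower triangle of a symmetric matrix column-wise."""
    q = M.shape[0]
    return np.concatenate([M[i:, i] for i in range(q)])


def unvech(v: np.ndarray, q: int) -> np.ndarray:
    M = np.zeros((q, q))
    pos = 0
    for i in range(q):
        m = q - i
        M[i:, i] = v[pos:pos + m]
        M[i, i:] = v[pos:pos + m]
        pos += m
    return M


_EIG_CLIP = 40.0  # |eigenvalues| of log D are kept below this


def pack_cov(D: np.ndarray) -> np.ndarray:
    """``vech`` of the matrix logarithm of a positive-definite matrix."""
    w, V = linalg.eigh(D)
    if np.any(w <= 0):
        raise ValueError("covariance matrix is not positive definite")
    L = (V * np.log(w)) @ V.T
    return vech(0.5 * (L + L.T))


def unpack_cov(v: np.ndarray, q: int) -> np.ndarray:
    """Inverse map: symmetric-matrix exponential via eigendecomposition
    (always positive definite, robust for extreme parameter excursions)."""
    L = unvech(v, q)
    w, V = linalg.eigh(L)
    D = (V * np.exp(np.clip(w, -_EIG_CLIP, _EIG_CLIP))) @ V.T
    return 0.5 * (D + D.T)


def _expm_frechet_sym(L: np.ndarray, directions) -> List[np.ndarray]:
    """Frechet derivatives of the symmetric matrix exponential along each
    direction, by the Daleckii-Krein formula on the eigenbasis of L."""
    w, V = linalg.eigh(L)
    wc = np.clip(w, -_EIG_CLIP, _EIG_CLIP)
    ew = np.exp(wc)
    diff = wc[:, None] - wc[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ew[:, None] - ew[None, :]) / diff
    same = np.abs(diff) < 1e-12
    F[same] = np.broadcast_to(ew[:, None], F.shape)[same]
    out = []
    for E in directions:
        out.append(V @ (F * (V.T @ E @ V)) @ V.T)
    return out


def _vech_bases(q: int) -> List[np.ndarray]:
    """Symmetric basis matrices matching the vech ordering."""
    out = []
    for i in range(q):
        for j in range(i, q):
            E = np.zeros((q, q))
            E[j, i] = 1.0
            E[i, j] = 1.0
            out.append(E)
    return out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class JointParams:
    """All parameter blocks of the joint model."""

    theta_l: LmmParams
    theta_v: Optional[VisitParams] = None
    theta_s: List[CauseParams] = field(default_factory=list)


@dataclass
class FitResult:
    params: JointParams
    packed: np.ndarray
    names: List[str]
    cov: Optional[np.ndarray]
    se: Optional[np.ndarray]
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    grad_norm: float
    config: dict = field(default_factory=dict)

    def ci(self, level: float = 0.95) -> np.ndarray:
        """Wald CIs on the packed (transformed) scale, shape (n_par, 2)."""
        from scipy.stats import norm

        if self.se is None:
            raise ValueError("standard errors unavailable (singular Hessian)")
        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.packed - z * self.se, self.packed + z * self.se])

    def summary_table(self):
        import pandas as pd

        se = self.se if self.se is not None else np.full_like(self.packed, np.nan)
        lo = self.packed - 1.959963984540054 * se
        hi = self.packed + 1.959963984540054 * se
        return pd.DataFrame(
            {"name": self.names, "estimate": self.packed, "se": se,
             "ci_low": lo, "ci_high": hi}
        )


def _safe_nll(model: "JointModel", prepared):
    """Negative log-likelihood + gradient, returning a large finite penalty
    when a line-search excursion leaves the numerically valid region."""

    def nll(v):
        try:
            ll, g = model.loglik_and_score(v, prepared)
        except (ValueError, linalg.LinAlgError):
            return 1e10, np.zeros_like(v)
        if not np.isfinite(ll) or not np.all(np.isfinite(g)):
            return 1e10, np.zeros_like(v)
        return -ll, -g

    return nll


@dataclass
class _PreparedSubject:
    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    visit: Optional[_Prepared]
    causes: List[_Prepared]
    # sufficient statistics of the marker block (theta-independent); the
    # Gaussian marginal and the posterior of b|Y only need these q x q / q x p
    # cross-products, never the n_i-dimensional arrays
    XtX: np.ndarray = None
    XtY: np.ndarray = None
    YtY: float = 0.0
    ZtX: np.ndarray = None
    ZtY: np.ndarray = None
    ZtZ: np.ndarray = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.XtX is None:
            X, Z, Y = self.X, self.Z, self.Y
            self.XtX = X.T @ X
            self.XtY = X.T @ Y
            self.YtY = float(Y @ Y)
            self.ZtX = Z.T @ X
            self.ZtY = Z.T @ Y
            self.ZtZ = Z.T @ Z
            self.n = Y.shape[0]


# ---------------------------------------------------------------------------
# the joint model
# ---------------------------------------------------------------------------

class JointModel:
    """Joint model structure: marker basis, optional visiting submodel,
    zero or more cause-specific hazards, and a quadrature rule.

    The same class covers the full joint model and all its reduced presets
    (e.g. "ignore the visiting process" simply omits ``visit_model``).
    """

    def __init__(
        self,
        marker_basis: MarkerBasis,
        q: int,
        p: int,
        visit_model: Optional[VisitProcessModel] = None,
        cause_models: Sequence[CauseModel] = (),
        rule: Optional[QuadratureRule] = None,
    ) -> None:
        self.marker_basis = marker_basis
        self.q = q
        self.p = p
        self.visit_model = visit_model
        self.cause_models = list(cause_models)
        self.rule = rule or QuadratureRule()
        self._nL = q * (q + 1) // 2
        self._bases = _vech_bases(q)

    # -- packing ------------------------------------------------------------

    def param_names(self) -> List[str]:
        names = [f"beta[{i}]" for i in range(self.p)]
        names += [f"logmD[{j},{i}]" for i in range(self.q) for j in range(i, self.q)]
        names += ["log_sigma2"]
        if self.visit_model is not None:
            vm = self.visit_model
            names += [f"visit:psi[{i}]" for i in range(vm.spline.n_coef)]
            names += [f"visit:gamma({f})" for f in vm.gamma_features]
            names += [f"visit:phi({f})" for f in vm.phi_features]
            if vm.assoc_m0:
                names += ["visit:alpha1(m0)"]
            if vm.assoc_slope:
                names += ["visit:alpha2(slope)"]
            if vm.frailty:
                names += ["visit:log_eta"]
        for k, cm in enumerate(self.cause_models, start=1):
            names += [f"cause{k}:psi[{i}]" for i in range(cm.spline.n_coef)]
            names += [f"cause{k}:gamma({f})" for f in cm.gamma_features]
            names += [f"cause{k}:phi({f})" for f in cm.phi_features]
            if cm.assoc_m0:
                names += [f"cause{k}:alpha1(m0)"]
            if cm.assoc_slope:
                names += [f"cause{k}:alpha2(slope)"]
        return names

    def pack(self, params: JointParams) -> np.ndarray:
        th = params.theta_l
        parts = [th.beta, pack_cov(th.D), [np.log(th.sigma2)]]
        if self.visit_model is not None:
            tv = params.theta_v
            parts += [tv.psi, tv.gamma, tv.phi]
            if self.visit_model.assoc_m0:
                parts += [[tv.alpha1]]
            if self.visit_model.assoc_slope:
                parts += [[tv.alpha2]]
            if self.visit_model.frailty:
                if tv.eta <= 0:
                    raise ValueError("frailty enabled but eta <= 0")
                parts += [[np.log(tv.eta)]]
        for cm, ts in zip(self.cause_models, params.theta_s):
            parts += [ts.psi, ts.gamma, ts.phi]
            if cm.assoc_m0:
                parts += [[ts.alpha1]]
            if cm.assoc_slope:
                parts += [[ts.alpha2]]
        vec = np.concatenate([np.asarray(x, dtype=float).ravel() for x in parts])
        if not np.all(np.isfinite(vec)):
            raise ValueError("packed parameter vector contains non-finite values")
        return vec

    def unpack(self, vec: np.ndarray) -> JointParams:
        vec = np.asarray(vec, dtype=float)
        pos = 0

        def take(m):
            nonlocal pos
            out = vec[pos:pos + m]
            pos += m
            return out

        beta = take(self.p)
        D = unpack_cov(take(self._nL), self.q)
        sigma2 = float(np.exp(take(1)[0]))
        theta_l = LmmParams(beta=beta, D=D, sigma2=sigma2)
        theta_v = None
        if self.visit_model is not None:
            vm = self.visit_model
            psi = take(vm.spline.n_coef)
            gamma = take(len(vm.gamma_features))
            phi = take(len(vm.phi_features))
            a1 = float(take(1)[0]) if vm.assoc_m0 else 0.0
            a2 = float(take(1)[0]) if vm.assoc_slope else 0.0
            eta = float(np.exp(take(1)[0])) if vm.frailty else 0.0
            theta_v = VisitParams(psi, gamma, phi, a1, a2, eta)
        theta_s = []
        for cm in self.cause_models:
            psi = take(cm.spline.n_coef)
            gamma = take(len(cm.gamma_features))
            phi = take(len(cm.phi_features))
            a1 = float(take(1)[0]) if cm.assoc_m0 else 0.0
            a2 = float(take(1)[0]) if cm.assoc_slope else 0.0
            theta_s.append(CauseParams(psi, gamma, phi, a1, a2))
        if pos != vec.shape[0]:
            raise ValueError("packed vector has wrong length")
        return JointParams(theta_l=theta_l, theta_v=theta_v, theta_s=theta_s)

    # -- data preparation ---------------------------------------------------

    def prepare(self, data) -> List[_PreparedSubject]:
        prepared = []
        for s in data:
            t = np.asarray(s.times, dtype=float)
            X = self.marker_basis.X(t, s.covariates)
            Z = self.marker_basis.Z(t, s.covariates)
            try:
                vis = (self.visit_model.prepare(s, self.marker_basis)
                       if self.visit_model is not None else None)
                causes = [cm.prepare(s, self.marker_basis, k)
                          for k, cm in enumerate(self.cause_models, start=1)]
            except ValueError as exc:
                raise ValueError(f"subject {s.id}: {exc}") from exc
            prepared.append(_PreparedSubject(
                Y=np.asarray(s.y, dtype=float), X=X, Z=Z, visit=vis, causes=causes))
        return prepared

    # -- likelihood and score ----------------------------------------------

    def _block_values(self, prep: _Prepared, psi, gamma, phi, a1, a2, beta, b_nodes):
        """Per-node event log-hazard sums, cumulative hazards, and the
        cached pieces the score assembly reuses."""
        M = b_nodes.shape[1]
        m0 = prep.x0 @ beta + prep.z0 @ b_nodes
        if prep.n_events:
            S_ev = (prep.ev_B @ psi + prep.ev_Fg @ gamma + prep.ev_Fp @ phi).sum() \
                + prep.n_events * a1 * m0 \
                + a2 * ((prep.ev_Xd @ beta).sum() + (prep.ev_Zd @ b_nodes).sum(axis=0))
        else:
            S_ev = np.zeros(M)
        gk_fixed = prep.gk_B @ psi + prep.gk_Fg @ gamma + prep.gk_Fp @ phi \
            + a2 * (prep.gk_Xd @ beta)
        md = prep.gk_Zd @ b_nodes
        expo = gk_fixed[:, None] + a2 * md
        np.clip(expo, -_EXP_CLIP, _EXP_CLIP, out=expo)
        h = np.exp(expo)
        em0 = np.exp(np.clip(a1 * m0, -_EXP_CLIP, _EXP_CLIP))
        Lam = (prep.gk_w @ h) * em0
        return m0, em0, S_ev, Lam, h, md

    def _block_score(self, prep: _Prepared, psi, gamma, phi, a1, a2, beta,
                     b_nodes, wq, cache, eta, vm_flags):
        """Gradient contributions of one hazard submodel block.

        Returns (d_psi, d_gamma, d_phi, d_a1, d_a2, d_logeta, d_beta).
        """
        m0, em0, S_ev, Lam, h, md = cache
        d = prep.n_events
        if eta > 0:
            a = 1.0 / eta
            rho = (a + d) / (a + Lam)
        else:
            rho = np.ones_like(Lam)
        c = wq * rho * em0                       # per-node scale of cumulative part
        hv = h @ c                               # (n_gk,)
        hw = prep.gk_w * hv
        d_psi = (prep.ev_B.sum(axis=0) if d else 0.0) - prep.gk_B.T @ hw
        d_gamma = (prep.ev_Fg.sum(axis=0) if d else 0.0) - prep.gk_Fg.T @ hw
        d_phi = (prep.ev_Fp.sum(axis=0) if d else 0.0) - prep.gk_Fp.T @ hw
        LamW = wq * rho * Lam                    # per-node weighted cumulative
        d_beta = np.zeros(beta.shape[0])
        d_a1 = 0.0
        d_a2 = 0.0
        # a1 direction and its beta chain (m0 = x0'beta + z0'b; only the x0
        # part carries a beta derivative)
        sumLamW = LamW.sum()
        if vm_flags[0]:
            d_a1 = d * float(wq @ m0) - float(m0 @ LamW)
        d_beta += a1 * prep.x0 * (d - sumLamW)
        # a2 direction: weighted integrals of hazard x slope
        md_full = (prep.gk_Xd @ beta)[:, None] + md
        wcol = (prep.gk_w[:, None] * h * md_full) @ c
        int_md = float(wcol.sum()) if np.ndim(wcol) else float(wcol)
        if vm_flags[1]:
            if d:
                ev_md = (prep.ev_Xd @ beta)[:, None] + prep.ev_Zd @ b_nodes
                d_a2 = float(wq @ ev_md.sum(axis=0)) - int_md
            else:
                d_a2 = -int_md
        if a2 != 0.0:
            d_beta += a2 * ((prep.ev_Xd.sum(axis=0) if d else 0.0)
                            - prep.gk_Xd.T @ hw)
        d_logeta = 0.0
        if eta > 0:
            a = 1.0 / eta
            dl_da = digamma(a + d) - digamma(a) + np.log(a) + 1.0 \
                - np.log(a + Lam) - (a + d) / (a + Lam)
            d_logeta = float(wq @ (-a * dl_da))
        return d_psi, d_gamma, d_phi, d_a1, d_a2, d_logeta, d_beta

    def loglik_and_score(self, vec: np.ndarray, prepared: Sequence[_PreparedSubject],
                         want_score: bool = True):
        params = self.unpack(vec)
        th = params.theta_l
        beta, D, sigma2 = th.beta, th.D, th.sigma2
        cf = linalg.cho_factor(D, lower=True)
        D_inv = linalg.cho_solve(cf, np.eye(self.q))
        L = unvech(np.asarray(vec[self.p:self.p + self._nL]), self.q)
        trL = float(np.trace(L))  # = log|D|
        if want_score:
            frechets = _expm_frechet_sym(L, self._bases)
            tr_bases = np.array([np.trace(E) for E in self._bases])
        total = 0.0
        grad = np.zeros(vec.shape[0]) if want_score else None
        nL = self._nL
        eye_q = np.eye(self.q)
        for ps in prepared:
            n_i = ps.n
            # marker marginal and posterior of b|Y via the q x q identities
            # |V| = sigma^{2n} |D| |prec| and Woodbury on V^{-1}
            prec = D_inv + ps.ZtZ / sigma2
            Lc = np.linalg.cholesky(prec)
            Zr = (ps.ZtY - ps.ZtX @ beta) / sigma2
            mu = linalg.cho_solve((Lc, True), Zr)
            rtr = ps.YtY - 2.0 * (beta @ ps.XtY) + beta @ (ps.XtX @ beta)
            quad = rtr / sigma2 - float(Zr @ mu)
            logdetV = n_i * np.log(sigma2) + trL + 2.0 * np.log(np.diag(Lc)).sum()
            ll_marker = float(-0.5 * n_i * np.log(2 * np.pi)
                              - 0.5 * logdetV - 0.5 * quad)
            C = linalg.cho_solve((Lc, True), eye_q)
            post = PosteriorRE(mu=mu, C=0.5 * (C + C.T), B=Lc.T)

            caches = {}

            def cond(b_nodes):
                vals = np.zeros(b_nodes.shape[1])
                if ps.visit is not None:
                    tv = params.theta_v
                    cv = self._block_values(ps.visit, tv.psi, tv.gamma, tv.phi,
                                            tv.alpha1, tv.alpha2, beta, b_nodes)
                    caches["visit"] = cv
                    m0, em0, S_ev, Lam, h, md = cv
                    if tv.eta > 0:
                        a = 1.0 / tv.eta
                        dct = ps.visit.n_events
                        vals += S_ev + gammaln(a + dct) - gammaln(a) \
                            + a * np.log(a) - (a + dct) * np.log(a + Lam)
                    else:
                        vals += S_ev - Lam
                for k, prep_c in enumerate(ps.causes):
                    tsk = params.theta_s[k]
                    cc = self._block_values(prep_c, tsk.psi, tsk.gamma, tsk.phi,
                                            tsk.alpha1, tsk.alpha2, beta, b_nodes)
                    caches[("cause", k)] = cc
                    vals += cc[2] - cc[3]
                return vals

            if ps.visit is None and not ps.causes:
                # marker-only model: integral is identically 1
                b_nodes = None
                log_marg = 0.0
                if want_score:
                    _, wq, b_nodes = marginalize_re(cond, post, self.rule)
            else:
                log_marg, wq, b_nodes = marginalize_re(cond, post, self.rule)
            total += ll_marker + log_marg

            if not want_score:
                continue

            # complete-data score averaged with the posterior node weights,
            # assembled from the q-dimensional sufficient statistics:
            # X'(r - Z b) and ||r - Z b||^2 expand in cross-products
            b_bar = b_nodes @ wq
            Xtr = ps.XtY - ps.XtX @ beta
            grad[: self.p] += (Xtr - ps.ZtX.T @ b_bar) / sigma2
            ZtZb = ps.ZtZ @ b_nodes
            rss = rtr - 2.0 * float((sigma2 * Zr) @ b_bar) \
                + float(((b_nodes * ZtZb).sum(axis=0)) @ wq)
            grad[self.p + nL] += -0.5 * n_i + 0.5 * rss / sigma2
            U = D_inv @ b_nodes
            S_b = (U * wq) @ U.T
            for m in range(nL):
                grad[self.p + m] += -0.5 * tr_bases[m] + 0.5 * float(np.sum(frechets[m] * S_b))

            pos = self.p + nL + 1
            if ps.visit is not None:
                vm = self.visit_model
                tv = params.theta_v
                d_psi, d_gam, d_phi, d_a1, d_a2, d_leta, d_beta = self._block_score(
                    ps.visit, tv.psi, tv.gamma, tv.phi, tv.alpha1, tv.alpha2, beta,
                    b_nodes, wq, caches["visit"], tv.eta if vm.frailty else 0.0,
                    (vm.assoc_m0, vm.assoc_slope))
                npsi, ng, nphi = vm.spline.n_coef, len(vm.gamma_features), len(vm.phi_features)
                grad[pos:pos + npsi] += d_psi; pos += npsi
                grad[pos:pos + ng] += d_gam; pos += ng
                grad[pos:pos + nphi] += d_phi; pos += nphi
                if vm.assoc_m0:
                    grad[pos] += d_a1; pos += 1
                if vm.assoc_slope:
                    grad[pos] += d_a2; pos += 1
                if vm.frailty:
                    grad[pos] += d_leta; pos += 1
                grad[: self.p] += d_beta
            for k, cm in enumerate(self.cause_models):
                tsk = params.theta_s[k]
                d_psi, d_gam, d_phi, d_a1, d_a2, _, d_beta = self._block_score(
                    ps.causes[k], tsk.psi, tsk.gamma, tsk.phi, tsk.alpha1, tsk.alpha2,
                    beta, b_nodes, wq, caches[("cause", k)], 0.0,
                    (cm.assoc_m0, cm.assoc_slope))
                npsi, ng, nphi = cm.spline.n_coef, len(cm.gamma_features), len(cm.phi_features)
                grad[pos:pos + npsi] += d_psi; pos += npsi
                grad[pos:pos + ng] += d_gam; pos += ng
                grad[pos:pos + nphi] += d_phi; pos += nphi
                if cm.assoc_m0:
                    grad[pos] += d_a1; pos += 1
                if cm.assoc_slope:
                    grad[pos] += d_a2; pos += 1
                grad[: self.p] += d_beta

        if want_score:
            return total, grad
        return total

    def loglik(self, params_or_vec, prepared) -> float:
        vec = params_or_vec if isinstance(params_or_vec, np.ndarray) \
            else self.pack(params_or_vec)
        return self.loglik_and_score(vec, prepared, want_score=False)

    def score(self, params_or_vec, prepared) -> np.ndarray:
        vec = params_or_vec if isinstance(params_or_vec, np.ndarray) \
            else self.pack(params_or_vec)
        return self.loglik_and_score(vec, prepared, want_score=True)[1]

    # -- initialisation -----------------------------------------------------

    def initialize(self, data, prepared=None) -> JointParams:
        """Stage-wise starting values: marker-only ML for theta_l, constant
        hazards for the baselines, zeros for all associations."""
        prepared = prepared if prepared is not None else self.prepare(data)
        # stage 1: marker-only fit
        times = np.concatenate([np.asarray(s.times, dtype=float) for s in data])
        if np.ptp(times) == 0:
            raise ValueError("degenerate marker data: all visit times identical")
        Xs = np.vstack([ps.X for ps in prepared])
        Ys = np.concatenate([ps.Y for ps in prepared])
        beta0, *_ = np.linalg.lstsq(Xs, Ys, rcond=None)
        resid = Ys - Xs @ beta0
        s2 = float(np.var(resid))
        D0 = np.eye(self.q) * max(s2, 1e-2)
        marker_model = JointModel(self.marker_basis, self.q, self.p, rule=self.rule)
        x0 = np.concatenate([beta0, pack_cov(D0), [np.log(max(s2 / 2.0, 1e-4))]])
        mprep = [_PreparedSubject(ps.Y, ps.X, ps.Z, None, []) for ps in prepared]
        res = optimize.minimize(_safe_nll(marker_model, mprep), x0, jac=True,
                                method="BFGS", options={"gtol": 1e-5, "maxiter": 500})
        th = marker_model.unpack(res.x).theta_l
        # keep the joint fit off the variance boundary: floor tiny eigenvalues
        w, V = linalg.eigh(th.D)
        floor = max(1e-2, 1e-3 * float(w.max()))
        if np.any(w < floor):
            D = (V * np.maximum(w, floor)) @ V.T
            th = LmmParams(th.beta, 0.5 * (D + D.T), th.sigma2)

        theta_v = None
        if self.visit_model is not None:
            vm = self.visit_model
            d_tot = sum(ps.visit.n_events for ps in prepared)
            if vm.scale == "gap":
                expo = sum(float(s.T) for s in data)  # total gap exposure = sum of gaps
            else:
                expo = sum(float(s.T) - float(s.times[0]) for s in data)
            lam = max(d_tot, 1) / max(expo, 1e-8)
            theta_v = VisitParams(
                psi=np.full(vm.spline.n_coef, np.log(lam)),
                gamma=np.zeros(len(vm.gamma_features)),
                phi=np.zeros(len(vm.phi_features)),
                alpha1=0.0, alpha2=0.0,
                eta=0.1 if vm.frailty else 0.0)
        theta_s = []
        for k, cm in enumerate(self.cause_models, start=1):
            d_k = sum(1 for s in data if int(s.cause) == k)
            expo = sum(float(s.T) for s in data)
            lam = max(d_k, 1) / max(expo, 1e-8)
            theta_s.append(CauseParams(
                psi=np.full(cm.spline.n_coef, np.log(lam)),
                gamma=np.zeros(len(cm.gamma_features)),
                phi=np.zeros(len(cm.phi_features)),
                alpha1=0.0, alpha2=0.0))
        return JointParams(theta_l=th, theta_v=theta_v, theta_s=theta_s)

    # -- fitting ------------------------------------------------------------

    def fit(self, data, init: Optional[JointParams] = None, gtol: float = 1e-5,
            maxiter: int = 500, compute_se: bool = True,
            config_echo: Optional[dict] = None) -> FitResult:
        prepared = self.prepare(data)
        start = init if init is not None else self.initialize(data, prepared)
        x0 = self.pack(start)
        nll = _safe_nll(self, prepared)
        # BFGS with restarts: a stale quasi-Newton Hessian occasionally makes
        # the line search fail ("precision loss") while the true gradient is
        # still large; restarting from the stop point with a fresh Hessian
        # recovers progress
        res = None
        n_iter = 0
        for _ in range(4):
            res_k = optimize.minimize(nll, x0, jac=True, method="BFGS",
                                      options={"gtol": gtol, "maxiter": maxiter})
            n_iter += int(res_k.nit)
            if res is not None and res_k.fun > res.fun + 1e-10:
                break  # restart made things worse; keep the previous state
            res = res_k
            x0 = res_k.x
            if res_k.success or res_k.nit == 0 \
                    or np.max(np.abs(res_k.jac)) < 1e-3 * (1.0 + abs(res_k.fun)):
                break
        vec = res.x
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success) or grad_norm < 1e-3 * (1.0 + abs(res.fun))
        if not converged:
            logger.warning("BFGS did not converge: %s (|g|_inf=%.2e)", res.message, grad_norm)
        cov = se = None
        if compute_se:
            H = self._hessian_fd(vec, prepared)
            # flat (no-information) directions make the FD Hessian's smallest
            # eigenvalues numerically zero or slightly negative; floor those
            # at 1e-8 * lambda_max, which yields honestly huge SEs there.
            # A substantially negative eigenvalue means the point is not a
            # maximum and SEs are withheld.
            w, V = linalg.eigh(H)
            wmax = float(w.max()) if w.size else 0.0
            if wmax <= 0 or w.min() < -1e-5 * wmax:
                logger.warning("Hessian not positive definite; "
                               "standard errors unavailable")
            else:
                w_f = np.maximum(w, 1e-8 * wmax)
                cov = (V / w_f) @ V.T
                se = np.sqrt(np.diag(cov))
        ll = -res.fun
        k = vec.shape[0]
        return FitResult(
            params=self.unpack(vec), packed=vec, names=self.param_names(),
            cov=cov, se=se, loglik=float(ll), aic=float(2 * k - 2 * ll),
            converged=converged, n_iter=n_iter, grad_norm=grad_norm,
            config=config_echo or {})

    def _hessian_fd(self, vec: np.ndarray, prepared, step: float = 1e-4) -> np.ndarray:
        """Hessian of the negative log-likelihood by central differences of
        the analytic score (step 1e-4 * (1 + |theta|) per coordinate)."""
        k = vec.shape[0]
        H = np.zeros((k, k))
        for i in range(k):
            h = step * (1.0 + abs(vec[i]))
            vp = vec.copy(); vp[i] += h
            vm = vec.copy(); vm[i] -= h
            gp = self.loglik_and_score(vp, prepared)[1]
            gm = self.loglik_and_score(vm, prepared)[1]
            H[:, i] = -(gp - gm) / (2.0 * h)
        return 0.5 * (H + H.T)


def derived_mean_marker(fit: FitResult, basis: MarkerBasis, t: float,
                        covariates=None, p: Optional[int] = None) -> Tuple[float, float]:
    """Population-averaged marker value ``X(t)' beta_hat`` with delta-method SE.

    Uses the leading ``p`` entries of the packed covariance (the beta block).
    """
    beta = fit.params.theta_l.beta
    p = p if p is not None else beta.shape[0]
    x = basis.X(t, covariates)[0]
    est = float(x @ beta)
    if fit.cov is None:
        return est, float("nan")
    V = fit.cov[:p, :p]
    return est, float(np.sqrt(x @ V @ x))
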