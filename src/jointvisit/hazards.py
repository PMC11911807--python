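"""Hazard and intensity components of the joint model.

The visiting process is modelled either on the *gap-time* scale (proportional
hazards for the times between consecutive visits) or on the *calendar-time*
scale (proportional intensity of the visit counting process).  Both share the
same linear predictor structure

    log h = B(.)' psi + gamma' Xbar_v(t_ij) + phi' g_v{Ybar(t_ij)}
            + alpha_1 m_i(0) + alpha_2 m_i'(.),

with a cubic B-spline log-baseline, history features that are constant
between consecutive visits, and associations with the latent baseline value
``m_i(0)`` and current latent slope ``m_i'``.  Cause-specific hazards for the
competing terminal events have the same form on calendar time.  An optional
Gamma(1/eta, 1/eta) frailty multiplies the visiting hazard/intensity and is
marginalised in closed form.

Per-interval integrals use fixed 15-point Gauss-Kronrod panels, one per
polynomial-smooth piece (intervals are split at interior spline knots); all
quantities are vectorised over a matrix of random-effect nodes so that the
conditional likelihood at every quadrature node of
:func:`jointvisit.integration.marginalize_re` is computed in a handful of
matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import gammaln

from .integration import gk15_nodes
from .lmm import LmmParams, MarkerBasis

__all__ = [
    "SplineBasis",
    "VisitParams",
    "CauseParams",
    "VisitProcessModel",
    "CauseModel",
    "feature_matrix",
    "KNOWN_FEATURES",
    "log_baseline",
    "gap_hazard",
    "gap_loglik_conditional",
    "intensity_loglik_conditional",
    "frailty_marginal_loglik",
    "competing_loglik_conditional",
]

_EXP_CLIP = 700.0


# ---------------------------------------------------------------------------
# B-spline log-baseline
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Cubic B-spline basis for a log-baseline hazard/intensity.

    ``n_coef = len(interior_knots) + degree + 1``.  Inside the boundary the
    basis satisfies the partition of unity; outside it the *log-baseline* is
    extended linearly, continuous in value and first derivative, which keeps
    the optimisation finite for event times slightly beyond the knots.
    """

    interior_knots: Sequence[float]
    boundary: tuple
    degree: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if hi <= lo:
            raise ValueError("upper boundary knot must exceed the lower")
        inter = np.sort(np.asarray(self.interior_knots, dtype=float))
        if inter.size and (inter[0] <= lo or inter[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary")
        k = self.degree
        self._t = np.concatenate([np.full(k + 1, lo), inter, np.full(k + 1, hi)])
        self._n = len(inter) + k + 1
        eye = np.eye(self._n)
        self._spl = BSpline(self._t, eye, k, extrapolate=False)
        self._dspl = self._spl.derivative()

    @property
    def n_coef(self) -> int:
        return self._n

    @classmethod
    def from_times(cls, times: np.ndarray, n_interior: int = 3, degree: int = 3,
                   lower: float = 0.0) -> "SplineBasis":
        """Place interior knots at equally spaced quantiles of observed times."""
        times = np.asarray(times, dtype=float)
        times = times[times > lower]
        if times.size == 0:
            raise ValueError("no positive times to place spline knots on")
        hi = float(np.max(times))
        if n_interior > 0:
            qs = np.quantile(times, np.linspace(0, 1, n_interior + 2)[1:-1])
            # keep knots strictly interior and distinct
            qs = np.clip(qs, lower + 1e-8, hi - 1e-8)
            qs = np.unique(qs)
        else:
            qs = np.array([])
        return cls(interior_knots=qs, boundary=(lower, hi), degree=degree)

    def design(self, u) -> np.ndarray:
        """Basis rows ``B(u)``, one per element of ``u`` (linear extension
        outside the boundary)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        lo, hi = self.boundary
        uc = np.clip(u, lo, hi)
        rows = self._spl(uc)
        out = np.where(u < lo, u - lo, np.where(u > hi, u - hi, 0.0))
        if np.any(out != 0.0):
            rows = rows + out[:, None] * self._dspl(uc)
        return rows

    def design_deriv(self, u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        lo, hi = self.boundary
        uc = np.clip(u, lo, hi)
        return self._dspl(uc)

    def coef_for_linear(self, a: float, b: float) -> np.ndarray:
        """Coefficients representing ``a + b*u`` exactly on the basis
        (values at the Greville abscissae); the linear extension keeps the
        identity outside the boundary too."""
        k = self.degree
        greville = np.array([self._t[i + 1:i + 1 + k].mean()
                             for i in range(self._n)])
        return a + b * greville


def log_baseline(basis: SplineBasis, psi: np.ndarray, u) -> np.ndarray:
    """``B(u)' psi``; ``exp`` of it is the baseline hazard/intensity."""
    val = basis.design(u) @ np.asarray(psi, dtype=float)
    return float(val[0]) if np.isscalar(u) else val


# ---------------------------------------------------------------------------
# history features
# ---------------------------------------------------------------------------

KNOWN_FEATURES = ("last_y", "prev_gap", "t_ij", "visit_count", "mean_gap")


def feature_matrix(
    subject,
    names: Sequence[str],
    prev_gap_center: float = 0.15,
) -> np.ndarray:
    """History features, one row per inter-visit interval.

    Row ``j`` (0-based) summarises the history up to and including visit
    ``j`` and applies on ``[t_j, t_{j+1})`` (or, on the gap scale, to the gap
    starting at ``t_j``); features are constant within the interval and use
    no data beyond ``t_j``.

    Built-in names: ``last_y`` (most recent observed marker), ``prev_gap``
    (most recently completed gap minus ``prev_gap_center``; 0 before the
    first completed gap), ``t_ij`` (interval start time), ``visit_count``
    (number of visits made so far), ``mean_gap`` (mean completed gap minus
    the centring constant; 0 before the first).  Any other name is looked up
    in the subject's baseline covariates.
    """
    t = np.asarray(subject.times, dtype=float)
    y = np.asarray(subject.y, dtype=float)
    n = t.shape[0]
    j = np.arange(n)
    cols = []
    for name in names:
        if name == "last_y":
            cols.append(y)
        elif name == "t_ij":
            cols.append(t)
        elif name == "prev_gap":
            col = np.zeros(n)
            if n > 1:
                col[1:] = np.diff(t) - prev_gap_center
            cols.append(col)
        elif name == "visit_count":
            cols.append((j + 1).astype(float))
        elif name == "mean_gap":
            col = np.zeros(n)
            if n > 1:
                col[1:] = t[1:] / np.arange(1, n) - prev_gap_center
            cols.append(col)
        else:
            try:
                val = subject.covariates[name]
            except KeyError as exc:
                raise KeyError(
                    f"unknown history feature or covariate {name!r}; "
                    f"built-ins are {KNOWN_FEATURES}"
                ) from exc
            cols.append(np.full(n, float(val)))
    if not cols:
        return np.zeros((n, 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class VisitParams:
    """theta_v = (psi_v, gamma_v, phi_v, alpha_v1, alpha_v2, eta)."""

    psi: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    alpha1: float = 0.0
    alpha2: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if self.eta < 0:
            raise ValueError("frailty variance eta must be nonnegative")


@dataclass
class CauseParams:
    """theta_sk = (psi_sk, gamma_sk, phi_sk, alpha_sk1, alpha_sk2)."""

    psi: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    alpha1: float = 0.0
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))


# ---------------------------------------------------------------------------
# prepared per-subject geometry
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    """Precomputed design arrays for one subject and one hazard submodel.

    Event part (one row per uncensored gap / observed arrival / cause event):
    ``ev_B`` spline rows, ``ev_Fg``/``ev_Fp`` feature rows, ``ev_Xd``/``ev_Zd``
    slope design rows.  Integral part (all 15-point Gauss-Kronrod nodes of
    all interval pieces flattened): ``gk_B``, ``gk_Fg``, ``gk_Fp``, ``gk_w``
    (weights incl. interval jacobians), ``gk_Xd``/``gk_Zd``, and ``gk_piece``
    mapping each node to its interval.
    """

    n_events: int
    ev_B: np.ndarray
    ev_Fg: np.ndarray
    ev_Fp: np.ndarray
    ev_Xd: np.ndarray
    ev_Zd: np.ndarray
    gk_B: np.ndarray
    gk_Fg: np.ndarray
    gk_Fp: np.ndarray
    gk_w: np.ndarray
    gk_Xd: np.ndarray
    gk_Zd: np.ndarray
    x0: np.ndarray
    z0: np.ndarray


def _flatten_intervals(bounds, basis_time, spline, marker_basis, covariates,
                       Fg, Fp, global_offset):
    """Flatten GK nodes of the interval pieces.

    ``bounds``: list of (a, b) per piece (on the scale the spline lives on);
    ``basis_time``: 'local' means the spline argument is the node value
    itself while the slope is evaluated at ``global_offset[piece] + node``
    (gap scale); 'global' means both use the node value (calendar scale).
    """
    knots = np.asarray(spline.interior_knots, dtype=float)
    Bs, ws, Xds, Zds, Fgs, Fps, pieces = [], [], [], [], [], [], []
    for idx, (a, b) in enumerate(bounds):
        if b <= a:
            continue
        # one GK15 panel per polynomial-smooth piece: split at spline knots
        inner = knots[(knots > a + 1e-12) & (knots < b - 1e-12)]
        edges = np.concatenate([[a], inner, [b]])
        xs, wsub = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            x1, w1 = gk15_nodes(lo, hi)
            xs.append(x1)
            wsub.append(w1)
        x = np.concatenate(xs)
        w = np.concatenate(wsub)
        tglob = x + (global_offset[idx] if basis_time == "local" else 0.0)
        Bs.append(spline.design(x))
        ws.append(w)
        Xds.append(marker_basis.dX(tglob, covariates))
        Zds.append(marker_basis.dZ(tglob, covariates))
        Fgs.append(np.repeat(Fg[idx][None, :], len(x), axis=0))
        Fps.append(np.repeat(Fp[idx][None, :], len(x), axis=0))
        pieces.append(np.full(len(x), idx))
    if not Bs:
        n_psi = spline.n_coef
        return (np.zeros((0, n_psi)), np.zeros((0, Fg.shape[1])),
                np.zeros((0, Fp.shape[1])), np.zeros(0),
                np.zeros((0, 0)), np.zeros((0, 0)), np.zeros(0, dtype=int))
    return (np.vstack(Bs), np.vstack(Fgs), np.vstack(Fps), np.concatenate(ws),
            np.vstack(Xds), np.vstack(Zds), np.concatenate(pieces))


@dataclass
class VisitProcessModel:
    """Structure of the visiting submodel (parameters live in VisitParams).

    ``scale`` is ``"gap"`` (proportional hazards for times between visits)
    or ``"calendar"`` (proportional intensity of the counting process).
    """

    scale: str
    spline: SplineBasis
    gamma_features: Sequence[str] = ()
    phi_features: Sequence[str] = ("last_y",)
    assoc_m0: bool = True
    assoc_slope: bool = True
    frailty: bool = False
    prev_gap_center: float = 0.15

    def __post_init__(self) -> None:
        if self.scale not in ("gap", "calendar"):
            raise ValueError("visiting-process scale must be 'gap' or 'calendar'")

    def prepare(self, subject, marker_basis: MarkerBasis) -> _Prepared:
        t = np.asarray(subject.times, dtype=float)
        T = float(subject.T)
        n = t.shape[0]
        if T < t[-1] - 1e-12:
            raise ValueError(f"subject {subject.id}: follow-up T={T} precedes last visit")
        cov = subject.covariates
        Fg = feature_matrix(subject, self.gamma_features, self.prev_gap_center)
        Fp = feature_matrix(subject, self.phi_features, self.prev_gap_center)
        ends = np.append(t[1:], T)
        if self.scale == "gap":
            gaps = ends - t
            bounds = [(0.0, g) for g in gaps]
            ev_times = gaps[: n - 1]            # observed gap lengths
            ev_slope_t = t[: n - 1] + ev_times  # = t[1:]
            offs = t
        else:
            bounds = [(t[j], ends[j]) for j in range(n)]
            ev_times = t[1:]                    # arrival calendar times
            ev_slope_t = t[1:]
            offs = np.zeros(n)
        gk_B, gk_Fg, gk_Fp, gk_w, gk_Xd, gk_Zd, _ = _flatten_intervals(
            bounds, "local" if self.scale == "gap" else "global",
            self.spline, marker_basis, cov, Fg, Fp, offs)
        ev_B = self.spline.design(ev_times) if len(ev_times) else np.zeros((0, self.spline.n_coef))
        ev_Xd = marker_basis.dX(ev_slope_t, cov) if len(ev_slope_t) else np.zeros((0, len(marker_basis.X(0.0, cov)[0])))
        ev_Zd = marker_basis.dZ(ev_slope_t, cov) if len(ev_slope_t) else np.zeros((0, len(marker_basis.Z(0.0, cov)[0])))
        return _Prepared(
            n_events=n - 1,
            ev_B=ev_B, ev_Fg=Fg[: n - 1], ev_Fp=Fp[: n - 1],
            ev_Xd=ev_Xd, ev_Zd=ev_Zd,
            gk_B=gk_B, gk_Fg=gk_Fg, gk_Fp=gk_Fp, gk_w=gk_w,
            gk_Xd=gk_Xd, gk_Zd=gk_Zd,
            x0=marker_basis.X(0.0, cov)[0], z0=marker_basis.Z(0.0, cov)[0],
        )


@dataclass
class CauseModel:
    """Structure of one cause-specific hazard (calendar time)."""

    spline: SplineBasis
    gamma_features: Sequence[str] = ()
    phi_features: Sequence[str] = ("last_y",)
    assoc_m0: bool = True
    assoc_slope: bool = True
    prev_gap_center: float = 0.15

    def prepare(self, subject, marker_basis: MarkerBasis, cause_index: int) -> _Prepared:
        t = np.asarray(subject.times, dtype=float)
        T = float(subject.T)
        n = t.shape[0]
        cov = subject.covariates
        Fg = feature_matrix(subject, self.gamma_features, self.prev_gap_center)
        Fp = feature_matrix(subject, self.phi_features, self.prev_gap_center)
        ends = np.append(t[1:], T)
        bounds = [(t[j], ends[j]) for j in range(n)]
        gk_B, gk_Fg, gk_Fp, gk_w, gk_Xd, gk_Zd, _ = _flatten_intervals(
            bounds, "global", self.spline, marker_basis, cov, Fg, Fp, np.zeros(n))
        event = int(subject.cause) == cause_index
        if event:
            ev_B = self.spline.design([T])
            ev_Fg = Fg[-1:][:]
            ev_Fp = Fp[-1:][:]
            ev_Xd = marker_basis.dX([T], cov)
            ev_Zd = marker_basis.dZ([T], cov)
            n_ev = 1
        else:
            p = len(marker_basis.X(0.0, cov)[0])
            q = len(marker_basis.Z(0.0, cov)[0])
            ev_B = np.zeros((0, self.spline.n_coef))
            ev_Fg = np.zeros((0, Fg.shape[1]))
            ev_Fp = np.zeros((0, Fp.shape[1]))
            ev_Xd = np.zeros((0, p))
            ev_Zd = np.zeros((0, q))
            n_ev = 0
        return _Prepared(
            n_events=n_ev,
            ev_B=ev_B, ev_Fg=ev_Fg, ev_Fp=ev_Fp, ev_Xd=ev_Xd, ev_Zd=ev_Zd,
            gk_B=gk_B, gk_Fg=gk_Fg, gk_Fp=gk_Fp, gk_w=gk_w,
            gk_Xd=gk_Xd, gk_Zd=gk_Zd,
            x0=marker_basis.X(0.0, cov)[0], z0=marker_basis.Z(0.0, cov)[0],
        )


# ---------------------------------------------------------------------------
# vectorised conditional log-likelihood pieces
# ---------------------------------------------------------------------------

def _linear_predictors(prep: _Prepared, psi, gamma, phi, alpha1, alpha2, beta, b_nodes):
    """Event log-hazard sums and cumulative hazards at every b node.

    Returns ``(S_ev, Lam)``: ``S_ev[m]`` is the sum of event-term
    log-hazards and ``Lam[m]`` the total integrated hazard for node ``m``.
    """
    b_nodes = np.atleast_2d(b_nodes)
    m0 = prep.x0 @ beta + prep.z0 @ b_nodes  # (M,)
    ev_fixed = prep.ev_B @ psi + prep.ev_Fg @ gamma + prep.ev_Fp @ phi
    if prep.n_events:
        ev_md = prep.ev_Xd @ beta
        S_ev = ev_fixed.sum() + prep.n_events * alpha1 * m0 \
            + alpha2 * (ev_md.sum() + (prep.ev_Zd @ b_nodes).sum(axis=0))
    else:
        S_ev = np.zeros(b_nodes.shape[1])
    gk_fixed = prep.gk_B @ psi + prep.gk_Fg @ gamma + prep.gk_Fp @ phi \
        + alpha2 * (prep.gk_Xd @ beta)
    expo = gk_fixed[:, None] + alpha2 * (prep.gk_Zd @ b_nodes)
    np.clip(expo, -_EXP_CLIP, _EXP_CLIP, out=expo)
    Lam = prep.gk_w @ np.exp(expo)  # (M,)
    Lam = Lam * np.exp(np.clip(alpha1 * m0, -_EXP_CLIP, _EXP_CLIP))
    return S_ev, Lam


def _frailty_logmarg(S_ev: np.ndarray, Lam: np.ndarray, d: int, eta: float) -> np.ndarray:
    """Closed-form Gamma(1/eta, 1/eta) frailty mixture of a Poisson-type
    likelihood with ``d`` events and cumulative hazard ``Lam``."""
    a = 1.0 / eta
    return (S_ev + gammaln(a + d) - gammaln(a) + a * np.log(a)
            - (a + d) * np.log(a + Lam))


def visit_conditional_loglik(prep: _Prepared, params: VisitParams,
                             theta_l: LmmParams, b_nodes: np.ndarray) -> np.ndarray:
    """log f(N_i^obs | Y_i, b) at each random-effect node (frailty-
    marginalised when eta > 0)."""
    S_ev, Lam = _linear_predictors(prep, params.psi, params.gamma, params.phi,
                                   params.alpha1, params.alpha2, theta_l.beta, b_nodes)
    if params.eta > 0:
        return _frailty_logmarg(S_ev, Lam, prep.n_events, params.eta)
    return S_ev - Lam


def cause_conditional_loglik(prep: _Prepared, params: CauseParams,
                             theta_l: LmmParams, b_nodes: np.ndarray) -> np.ndarray:
    """Contribution of one cause to log f(T_i, K_i | Y_i, b) at each node."""
    S_ev, Lam = _linear_predictors(prep, params.psi, params.gamma, params.phi,
                                   params.alpha1, params.alpha2, theta_l.beta, b_nodes)
    return S_ev - Lam


# ---------------------------------------------------------------------------
# single-b operation surface (used directly in tests and small analyses)
# ---------------------------------------------------------------------------

def gap_hazard(u, j, subject, b, model: VisitProcessModel, params: VisitParams,
               marker_basis: MarkerBasis, theta_l: LmmParams, frailty_w: float = 1.0):
    """Gap-time visiting hazard at time-since-last-visit ``u`` for the gap
    starting at visit ``j`` (0-based)."""
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u_arr < 0):
        raise ValueError("gap time u must be nonnegative")
    t = np.asarray(subject.times, dtype=float)
    Fg = feature_matrix(subject, model.gamma_features, model.prev_gap_center)
    Fp = feature_matrix(subject, model.phi_features, model.prev_gap_center)
    cov = subject.covariates
    b = np.asarray(b, dtype=float)
    m0 = float(marker_basis.X(0.0, cov)[0] @ theta_l.beta + marker_basis.Z(0.0, cov)[0] @ b)
    tt = t[j] + u_arr
    md = marker_basis.dX(tt, cov) @ theta_l.beta + marker_basis.dZ(tt, cov) @ b
    lp = (model.spline.design(u_arr) @ params.psi + Fg[j] @ params.gamma
          + Fp[j] @ params.phi + params.alpha1 * m0 + params.alpha2 * md)
    h = frailty_w * np.exp(lp)
    return float(h[0]) if np.isscalar(u) else h


def _single_b(fn, prep, params, theta_l, b):
    out = fn(prep, params, theta_l, np.asarray(b, dtype=float).reshape(-1, 1))
    return float(out[0])


def gap_loglik_conditional(subject, b, model: VisitProcessModel, params: VisitParams,
                           marker_basis: MarkerBasis, theta_l: LmmParams) -> float:
    """Conditional log-likelihood of the observed visit times, gap scale,
    given ``b`` (no frailty marginalisation: eta is ignored here)."""
    if model.scale != "gap":
        raise ValueError("model is not on the gap scale")
    prep = model.prepare(subject, marker_basis)
    p = VisitParams(params.psi, params.gamma, params.phi, params.alpha1, params.alpha2, 0.0)
    return _single_b(visit_conditional_loglik, prep, p, theta_l, b)


def intensity_loglik_conditional(subject, b, model: VisitProcessModel, params: VisitParams,
                                 marker_basis: MarkerBasis, theta_l: LmmParams) -> float:
    """Conditional log-likelihood of the observed visit times, calendar
    scale, given ``b``."""
    if model.scale != "calendar":
        raise ValueError("model is not on the calendar scale")
    prep = model.prepare(subject, marker_basis)
    p = VisitParams(params.psi, params.gamma, params.phi, params.alpha1, params.alpha2, 0.0)
    return _single_b(visit_conditional_loglik, prep, p, theta_l, b)


def frailty_marginal_loglik(subject, b, model: VisitProcessModel, params: VisitParams,
                            marker_basis: MarkerBasis, theta_l: LmmParams) -> float:
    """Visiting-process log-likelihood with the gamma frailty integrated out
    in closed form (requires eta > 0)."""
    if params.eta <= 0:
        raise ValueError("frailty_marginal_loglik requires eta > 0")
    prep = model.prepare(subject, marker_basis)
    return _single_b(visit_conditional_loglik, prep, params, theta_l, b)


def competing_loglik_conditional(subject, b, models: Sequence[CauseModel],
                                 params_list: Sequence[CauseParams],
                                 marker_basis: MarkerBasis, theta_l: LmmParams) -> float:
    """log f(T_i, K_i | Y_i, b): sum of all cause-specific contributions."""
    K = len(models)
    if not (0 <= int(subject.cause) <= K):
        raise ValueError(f"unknown cause code {subject.cause} (K={K})")
    total = 0.0
    for k, (mod, par) in enumerate(zip(models, params_list), start=1):
        prep = mod.prepare(subject, marker_basis, k)
        total += _single_b(cause_conditional_loglik, prep, par, theta_l, b)
    return total
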