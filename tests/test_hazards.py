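"""Visiting-process and competing-risks hazard components."""

import numpy as np
import pytest
from scipy.special import gammaln

from jointvisit import (CauseModel, CauseParams, SplineBasis,
                        SubjectRecord, VisitParams, VisitProcessModel,
                        cd4_preset_basis, competing_loglik_conditional,
                        feature_matrix, frailty_marginal_loglik, gap_hazard,
                        gap_loglik_conditional, intensity_loglik_conditional,
                        log_baseline)
from conftest import constant_rate_visit_model, constant_spline


@pytest.fixture(scope="module")
def basis():
    return cd4_preset_basis()


# ---------------------------------------------------------------------------
# spline log-baseline
# ---------------------------------------------------------------------------

class TestSplineBaseline:
    def test_zero_coefficients_give_unit_baseline(self):
        sb = SplineBasis(interior_knots=[1.0, 2.0], boundary=(0.0, 5.0))
        u = np.linspace(0, 5, 11)
        assert np.allclose(np.exp(log_baseline(sb, np.zeros(sb.n_coef), u)), 1.0)

    def test_partition_of_unity_gives_constant(self):
        sb = SplineBasis(interior_knots=[0.5, 1.2, 3.0], boundary=(0.0, 6.0))
        c = -1.3
        u = np.linspace(0.0, 6.0, 200)
        assert np.allclose(log_baseline(sb, np.full(sb.n_coef, c), u), c, atol=1e-12)

    def test_linear_extension_outside_boundary(self):
        sb = SplineBasis(interior_knots=[1.0], boundary=(0.0, 2.0))
        psi = np.linspace(-1, 1, sb.n_coef)
        v2 = log_baseline(sb, psi, 2.0)
        v25, v3 = log_baseline(sb, psi, np.array([2.5, 3.0]))
        # linear in u beyond the boundary
        assert v3 - v25 == pytest.approx(v25 - v2, rel=1e-9)

    def test_coefficient_count(self):
        sb = SplineBasis(interior_knots=[1.0, 2.0, 3.0], boundary=(0.0, 5.0))
        assert sb.n_coef == 3 + 3 + 1


# ---------------------------------------------------------------------------
# history features
# ---------------------------------------------------------------------------

def test_feature_matrix_uses_only_past_data(toy_subject):
    F = feature_matrix(toy_subject, ["last_y", "t_ij", "prev_gap", "visit_count"])
    t = toy_subject.times
    assert np.allclose(F[:, 0], toy_subject.y)
    assert np.allclose(F[:, 1], t)
    assert F[0, 2] == 0.0  # no completed gap before the first visit
    assert np.allclose(F[1:, 2], np.diff(t) - 0.15)
    assert np.allclose(F[:, 3], [1, 2, 3, 4])


def test_feature_matrix_unknown_name_raises(toy_subject):
    with pytest.raises(KeyError, match="unknown history feature"):
        feature_matrix(toy_subject, ["not_a_feature"])


# ---------------------------------------------------------------------------
# gap hazard
# ---------------------------------------------------------------------------

class TestGapHazard:
    def test_all_zero_coefficients_give_unit_hazard(self, toy_subject, basis,
                                                    theta_l_true):
        model, params = constant_rate_visit_model(0.0)
        h = gap_hazard(np.array([0.1, 0.5, 1.0]), 0, toy_subject, np.zeros(3),
                       model, params, basis, theta_l_true)
        assert np.allclose(h, 1.0)

    def test_proportional_hazards_in_covariates(self, toy_subject, basis,
                                                theta_l_true):
        spline = constant_spline()
        model = VisitProcessModel(scale="gap", spline=spline,
                                  gamma_features=("W",), phi_features=(),
                                  assoc_m0=False, assoc_slope=False)
        gam = 0.7
        p1 = VisitParams(psi=np.zeros(spline.n_coef), gamma=[gam], phi=[])
        h1 = gap_hazard(0.3, 1, toy_subject, np.zeros(3), model, p1, basis,
                        theta_l_true)
        sub2 = SubjectRecord(id="s2", times=toy_subject.times, y=toy_subject.y,
                             T=toy_subject.T, cause=toy_subject.cause,
                             covariates={"W": 2.0})
        h2 = gap_hazard(0.3, 1, sub2, np.zeros(3), model, p1, basis, theta_l_true)
        assert h2 / h1 == pytest.approx(np.exp(gam), rel=1e-12)

    def test_hazard_ratio_per_unit_latent_slope(self, toy_subject, basis,
                                                theta_l_true):
        """With the study truths (alpha_v2 = 0.20) a one-unit higher latent
        slope multiplies the visiting hazard by e^0.20."""
        spline = constant_spline()
        model = VisitProcessModel(scale="gap", spline=spline,
                                  gamma_features=(), phi_features=(),
                                  assoc_m0=False, assoc_slope=True)
        params = VisitParams(psi=np.zeros(spline.n_coef), gamma=[], phi=[],
                             alpha2=0.20)
        u, j = 0.4, 1
        t_now = toy_subject.times[j] + u
        b1 = np.zeros(3)
        b2 = np.array([0.0, t_now + 1.0, 0.0])  # raises m'(t_now) by exactly 1
        h1 = gap_hazard(u, j, toy_subject, b1, model, params, basis, theta_l_true)
        h2 = gap_hazard(u, j, toy_subject, b2, model, params, basis, theta_l_true)
        assert h2 / h1 == pytest.approx(np.exp(0.20), rel=1e-9)

    def test_negative_gap_time_rejected(self, toy_subject, basis, theta_l_true):
        model, params = constant_rate_visit_model(0.0)
        with pytest.raises(ValueError, match="nonnegative"):
            gap_hazard(-0.1, 0, toy_subject, np.zeros(3), model, params, basis,
                       theta_l_true)


# ---------------------------------------------------------------------------
# conditional likelihoods
# ---------------------------------------------------------------------------

class TestGapLikelihood:
    def test_exponential_closed_form(self, basis, theta_l_true):
        lam = 1.7
        u = 0.8
        sub = SubjectRecord(id=1, times=[0.0, u], y=[18.0, 19.0], T=u, cause=0)
        model, params = constant_rate_visit_model(np.log(lam))
        ll = gap_loglik_conditional(sub, np.zeros(3), model, params, basis,
                                    theta_l_true)
        assert ll == pytest.approx(np.log(lam) - lam * u, rel=1e-10)

    def test_censored_only_gap(self, basis, theta_l_true):
        lam, u = 2.2, 0.6
        sub = SubjectRecord(id=1, times=[0.0], y=[18.0], T=u, cause=0)
        model, params = constant_rate_visit_model(np.log(lam))
        ll = gap_loglik_conditional(sub, np.zeros(3), model, params, basis,
                                    theta_l_true)
        assert ll == pytest.approx(-lam * u, rel=1e-10)

    def test_integrated_hazard_matches_dense_trapezoid(self, toy_subject, basis,
                                                       theta_l_true, rng):
        spline = SplineBasis(interior_knots=[0.3, 0.8], boundary=(0.0, 3.0))
        model = VisitProcessModel(scale="gap", spline=spline,
                                  gamma_features=("t_ij",),
                                  phi_features=("last_y",))
        params = VisitParams(psi=rng.normal(scale=0.3, size=spline.n_coef),
                             gamma=[-0.05], phi=[0.02], alpha1=0.01, alpha2=0.15)
        b = rng.normal(scale=0.5, size=3)
        ll = gap_loglik_conditional(toy_subject, b, model, params, basis,
                                    theta_l_true)
        # oracle: event terms from the pointwise hazard + dense trapezoid
        t = toy_subject.times
        gaps = np.diff(np.append(t, toy_subject.T))
        total = 0.0
        for j, g in enumerate(gaps):
            uu = np.linspace(0, g, 10_000)
            h = gap_hazard(uu, j, toy_subject, b, model, params, basis,
                           theta_l_true)
            total -= np.trapezoid(h, uu)
            if j < len(t) - 1:
                total += np.log(gap_hazard(g, j, toy_subject, b, model, params,
                                           basis, theta_l_true))
        assert ll == pytest.approx(total, rel=1e-6)


class TestIntensityLikelihood:
    def test_poisson_process_closed_form(self, basis, theta_l_true):
        lam = 1.4
        sub = SubjectRecord(id=1, times=[0.0, 0.5, 1.3, 2.0], y=[18.0] * 4,
                            T=2.6, cause=0)
        model, params = constant_rate_visit_model(np.log(lam), scale="calendar")
        ll = intensity_loglik_conditional(sub, np.zeros(3), model, params,
                                          basis, theta_l_true)
        d = 3  # arrivals after the baseline visit
        assert ll == pytest.approx(d * np.log(lam) - lam * 2.6, rel=1e-10)

    def test_time_varying_baseline_matches_analytic_integral(self, basis,
                                                             theta_l_true):
        # log-intensity a + b*t on a single interval; closed-form integral
        a, bcoef = -0.2, 0.35
        sub = SubjectRecord(id=1, times=[0.0], y=[18.0], T=2.0, cause=0)
        spline = SplineBasis(interior_knots=[], boundary=(0.0, 2.0), degree=1)
        # degree-1 basis {1-t/2, t/2}: coefficients (a, a+2b) give a + b t
        model = VisitProcessModel(scale="calendar", spline=spline,
                                  gamma_features=(), phi_features=(),
                                  assoc_m0=False, assoc_slope=False)
        params = VisitParams(psi=[a, a + 2 * bcoef], gamma=[], phi=[])
        ll = intensity_loglik_conditional(sub, np.zeros(3), model, params,
                                          basis, theta_l_true)
        expected = -(np.exp(a + bcoef * 2.0) - np.exp(a)) / bcoef
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_reduces_to_gap_model_for_constant_memoryless_case(self, basis,
                                                               theta_l_true):
        """Constant baseline and no slope association: gap and calendar
        likelihoods coincide (the same exponential process)."""
        lam = 0.9
        sub = SubjectRecord(id=1, times=[0.0, 0.7, 1.1], y=[18.0, 20.0, 21.0],
                            T=1.8, cause=0)
        mg, pg = constant_rate_visit_model(np.log(lam), scale="gap")
        mc, pc = constant_rate_visit_model(np.log(lam), scale="calendar")
        llg = gap_loglik_conditional(sub, np.zeros(3), mg, pg, basis, theta_l_true)
        llc = intensity_loglik_conditional(sub, np.zeros(3), mc, pc, basis,
                                           theta_l_true)
        assert llg == pytest.approx(llc, rel=1e-10)


class TestFrailtyMarginal:
    def _model(self, eta):
        spline = constant_spline()
        model = VisitProcessModel(scale="gap", spline=spline,
                                  gamma_features=(), phi_features=("last_y",),
                                  assoc_m0=True, assoc_slope=True, frailty=True)
        params = VisitParams(psi=np.full(spline.n_coef, -0.1), gamma=[],
                             phi=[0.02], alpha1=0.01, alpha2=0.1, eta=eta)
        return model, params

    def test_degenerate_frailty_limit(self, toy_subject, basis, theta_l_true):
        model, params = self._model(1e-6)
        ll_frail = frailty_marginal_loglik(toy_subject, np.zeros(3), model,
                                           params, basis, theta_l_true)
        ll_plain = gap_loglik_conditional(toy_subject, np.zeros(3), model,
                                          params, basis, theta_l_true)
        assert ll_frail == pytest.approx(ll_plain, rel=1e-4)

    def test_no_event_laplace_transform(self, basis, theta_l_true):
        eta = 0.5
        sub = SubjectRecord(id=1, times=[0.0], y=[18.0], T=1.2, cause=0)
        model, params = self._model(eta)
        ll = frailty_marginal_loglik(sub, np.zeros(3), model, params, basis,
                                     theta_l_true)
        p0 = VisitParams(params.psi, params.gamma, params.phi, params.alpha1,
                         params.alpha2, 0.0)
        Lam = -gap_loglik_conditional(sub, np.zeros(3), model, p0, basis,
                                      theta_l_true)
        assert ll == pytest.approx(-np.log1p(eta * Lam) / eta, rel=1e-10)

    def test_matches_gauss_laguerre_over_frailty(self, toy_subject, basis,
                                                 theta_l_true):
        """Closed-form gamma mixture vs 60-point Gauss-Laguerre."""
        eta = 0.6
        a = 1.0 / eta
        model, params = self._model(eta)
        b = np.array([0.2, -0.1, 0.3])
        ll = frailty_marginal_loglik(toy_subject, b, model, params, basis,
                                     theta_l_true)
        d = toy_subject.n_visits - 1

        def cond_ll(v):
            # conditional log-likelihood with the frailty fixed at v > 0:
            # S_ev + d log v - v * Lam  (shift the log-baseline by log v)
            pv = VisitParams(params.psi + np.log(v), params.gamma, params.phi,
                             params.alpha1, params.alpha2, 0.0)
            return gap_loglik_conditional(toy_subject, b, model, pv, basis,
                                          theta_l_true)

        l1, l2 = cond_ll(1.0), cond_ll(2.0)
        Lam = -(l2 - l1 - d * np.log(2.0))
        S_ev = l1 + Lam
        # Gauss-Laguerre (60 nodes) for the gamma mixture integral
        # L = e^{S_ev} a^a / Gamma(a) * int v^{a+d-1} e^{-(a+Lam) v} dv,
        # substituting x = (a+Lam) v to expose the e^{-x} weight
        x, w = np.polynomial.laguerre.laggauss(60)
        logI = (S_ev + a * np.log(a) - gammaln(a) - (a + d) * np.log(a + Lam)
                + np.log(np.sum(w * x ** (a + d - 1))))
        assert ll == pytest.approx(logI, rel=1e-6)

    def test_monotone_decreasing_in_cumulative_hazard(self, basis, theta_l_true):
        eta = 0.4
        model, params = self._model(eta)
        lls = []
        for T in (0.5, 1.0, 2.0, 4.0):
            sub = SubjectRecord(id=1, times=[0.0, 0.3], y=[18.0, 19.0], T=T,
                                cause=0)
            lls.append(frailty_marginal_loglik(sub, np.zeros(3), model, params,
                                               basis, theta_l_true))
        assert np.all(np.diff(lls) < 0)

    def test_requires_positive_eta(self, toy_subject, basis, theta_l_true):
        model, params = self._model(0.5)
        params = VisitParams(params.psi, params.gamma, params.phi,
                             params.alpha1, params.alpha2, 0.0)
        with pytest.raises(ValueError, match="eta"):
            frailty_marginal_loglik(toy_subject, np.zeros(3), model, params,
                                    basis, theta_l_true)


class TestCompetingRisks:
    def test_single_cause_constant_hazard(self, basis, theta_l_true):
        lam, T = 0.4, 2.5
        sub = SubjectRecord(id=1, times=[0.0], y=[18.0], T=T, cause=1)
        spline = constant_spline()
        model = CauseModel(spline=spline, gamma_features=(), phi_features=(),
                           assoc_m0=False, assoc_slope=False)
        params = CauseParams(psi=np.full(spline.n_coef, np.log(lam)), gamma=[],
                             phi=[])
        ll = competing_loglik_conditional(sub, np.zeros(3), [model], [params],
                                          basis, theta_l_true)
        assert ll == pytest.approx(np.log(lam) - lam * T, rel=1e-10)

    def test_two_causes_censored_all_cause_survival(self, basis, theta_l_true):
        lam1, lam2, T = 0.3, 0.7, 1.8
        sub = SubjectRecord(id=1, times=[0.0], y=[18.0], T=T, cause=0)
        spline = constant_spline()
        models = [CauseModel(spline=spline, gamma_features=(), phi_features=(),
                             assoc_m0=False, assoc_slope=False)] * 2
        params = [CauseParams(psi=np.full(spline.n_coef, np.log(l)), gamma=[],
                              phi=[]) for l in (lam1, lam2)]
        ll = competing_loglik_conditional(sub, np.zeros(3), models, params,
                                          basis, theta_l_true)
        assert ll == pytest.approx(-(lam1 + lam2) * T, rel=1e-10)

    def test_piecewise_covariates_match_dense_quadrature(self, toy_subject,
                                                         basis, theta_l_true,
                                                         rng):
        spline = SplineBasis(interior_knots=[1.0], boundary=(0.0, 3.0))
        model = CauseModel(spline=spline, gamma_features=("W",),
                           phi_features=("last_y",))
        params = CauseParams(psi=rng.normal(scale=0.3, size=spline.n_coef),
                             gamma=[0.4], phi=[-0.05], alpha1=-0.03, alpha2=-0.1)
        b = rng.normal(scale=0.5, size=3)
        toy_subject = SubjectRecord(id=toy_subject.id, times=toy_subject.times,
                                    y=toy_subject.y, T=toy_subject.T, cause=1,
                                    covariates=toy_subject.covariates)
        ll = competing_loglik_conditional(toy_subject, b, [model], [params],
                                          basis, theta_l_true)
        # oracle: hand-built piecewise hazard + dense trapezoid
        t = np.append(toy_subject.times, toy_subject.T)
        F = feature_matrix(toy_subject, ["W", "last_y"])
        m0 = basis.X(0.0)[0] @ theta_l_true.beta + basis.Z(0.0)[0] @ b

        def hz(tt, j):
            md = (basis.dX(tt) @ theta_l_true.beta + basis.dZ(tt) @ b)
            return np.exp(spline.design(tt) @ params.psi + 0.4 * F[j, 0]
                          - 0.05 * F[j, 1] - 0.03 * m0 - 0.1 * md)

        cum = 0.0
        for j in range(len(t) - 1):
            tt = np.linspace(t[j], t[j + 1], 10_000)
            cum += np.trapezoid(hz(tt, j), tt)
        jlast = toy_subject.n_visits - 1
        expected = float(np.log(hz(np.array([toy_subject.T]), jlast)[0])) - cum
        assert ll == pytest.approx(expected, rel=1e-6)

    def test_unknown_cause_code_rejected(self, toy_subject, basis, theta_l_true):
        sub = SubjectRecord(id=1, times=[0.0], y=[18.0], T=1.0, cause=3)
        spline = constant_spline()
        model = CauseModel(spline=spline, gamma_features=(), phi_features=(),
                           assoc_m0=False, assoc_slope=False)
        params = CauseParams(psi=np.zeros(spline.n_coef), gamma=[], phi=[])
        with pytest.raises(ValueError, match="cause"):
            competing_loglik_conditional(sub, np.zeros(3), [model], [params],
                                         basis, theta_l_true)


def test_likelihood_invariant_to_cause_relabelling(toy_subject, basis,
                                                  theta_l_true, rng):
    """Summing cause contributions is order-invariant."""
    spline = constant_spline()
    models = [CauseModel(spline=spline, gamma_features=("W",),
                         phi_features=("last_y",)) for _ in range(2)]
    par = [CauseParams(psi=rng.normal(size=spline.n_coef), gamma=[0.3],
                       phi=[0.1], alpha1=0.05, alpha2=-0.1) for _ in range(2)]
    sub0 = SubjectRecord(id=1, times=toy_subject.times, y=toy_subject.y,
                         T=toy_subject.T, cause=0,
                         covariates=toy_subject.covariates)
    b = rng.normal(size=3)
    ll_a = competing_loglik_conditional(sub0, b, models, par, basis, theta_l_true)
    ll_b = competing_loglik_conditional(sub0, b, models[::-1], par[::-1], basis,
                                        theta_l_true)
    assert ll_a == pytest.approx(ll_b, rel=1e-12)
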