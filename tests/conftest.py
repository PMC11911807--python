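import numpy as np
import pytest

from jointvisit import (LmmParams, SplineBasis, SubjectRecord, VisitParams,
                        VisitProcessModel, cd4_preset_basis)


@pytest.fixture(scope="session")
def preset_basis():
    return cd4_preset_basis()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theta_l_true():
    D = np.array([[16.0, -1.6, 0.0], [-1.6, 4.0, 0.0], [0.0, 0.0, 4.0]])
    return LmmParams(beta=np.array([17.20, 4.83, -2.80]), D=D, sigma2=4.0)


@pytest.fixture
def toy_subject():
    """Four visits over ~2 years, followed up to 2.5 years, cause-2 event."""
    return SubjectRecord(
        id="s1",
        times=np.array([0.0, 0.4, 1.1, 2.0]),
        y=np.array([18.0, 20.5, 21.0, 22.8]),
        T=2.5,
        cause=2,
        covariates={"W": 1.0},
    )


def constant_spline(value: float = 0.0, hi: float = 12.0) -> SplineBasis:
    """Basis on [0, hi] with no interior knots; equal coefficients give a
    constant log-baseline by partition of unity."""
    return SplineBasis(interior_knots=[], boundary=(0.0, hi))


def constant_rate_visit_model(log_rate: float, scale: str = "gap",
                              **kw) -> tuple[VisitProcessModel, VisitParams]:
    """Visiting model with constant baseline hazard exp(log_rate) and no
    covariate, marker, or latent terms."""
    spline = constant_spline()
    model = VisitProcessModel(scale=scale, spline=spline, gamma_features=(),
                              phi_features=(), assoc_m0=False,
                              assoc_slope=False, **kw)
    params = VisitParams(psi=np.full(spline.n_coef, log_rate), gamma=[],
                         phi=[], alpha1=0.0, alpha2=0.0)
    return model, params
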