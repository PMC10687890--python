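import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import multivariate_normal

from contactrsf import ctmm
from contactrsf.errors import FitFailureError, InsufficientDataError
from contactrsf.synthfix import simulate_family_track

# ---------------------------------------------------------------------------
# independent dense-covariance oracles


def ou_cov(t, sigma2, tau):
    d = np.abs(t[:, None] - t[None, :])
    return sigma2 * np.exp(-d / tau)


def ouf_cov(t, sigma2, tau_p, tau_v):
    d = np.abs(t[:, None] - t[None, :])
    return sigma2 * (tau_p * np.exp(-d / tau_p) - tau_v * np.exp(-d / tau_v)) / (tau_p - tau_v)


def dense_loglik(track, cov, mu):
    return multivariate_normal.logpdf(track.x, np.full(len(cov), mu[0]), cov) + \
        multivariate_normal.logpdf(track.y, np.full(len(cov), mu[1]), cov)


def sample_track(make_track, t, cov, mu, seed):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-9 * cov[0, 0] * np.eye(len(cov)))
    return make_track(t, mu[0] + L @ rng.standard_normal(len(t)),
                      mu[1] + L @ rng.standard_normal(len(t)))


# ---------------------------------------------------------------------------
# likelihood identities


class TestLikelihoodOracles:
    @pytest.mark.parametrize("R", [0.0, 25.0])
    def test_ou_matches_dense(self, make_track, R):
        rng = np.random.default_rng(10)
        t = np.sort(rng.uniform(0, 400, 40))
        cov = ou_cov(t, 1e4, 60.0) + R * np.eye(40)
        tr = sample_track(make_track, t, cov, (500.0, 300.0), 1)
        ll = ctmm.log_likelihood(tr, "OU", sigma2=1e4, tau_p=60.0, error_var=R, mu=(500.0, 300.0))
        assert ll == pytest.approx(dense_loglik(tr, cov, (500.0, 300.0)), abs=1e-6)

    def test_ouf_matches_dense(self, make_track):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 800, 50))
        cov = ouf_cov(t, 1e4, 90.0, 12.0)
        tr = sample_track(make_track, t, cov, (-40.0, 75.0), 2)
        ll = ctmm.log_likelihood(tr, "OUF", sigma2=1e4, tau_p=90.0, tau_v=12.0,
                                 error_var=0.0, mu=(-40.0, 75.0))
        assert ll == pytest.approx(dense_loglik(tr, cov, (-40.0, 75.0)), abs=1e-6)

    def test_iid_matches_dense(self, make_track):
        rng = np.random.default_rng(12)
        t = np.arange(30.0)
        cov = 400.0 * np.eye(30)
        tr = sample_track(make_track, t, cov, (5.0, -5.0), 3)
        ll = ctmm.log_likelihood(tr, "IID", sigma2=400.0, error_var=0.0, mu=(5.0, -5.0))
        assert ll == pytest.approx(dense_loglik(tr, cov, (5.0, -5.0)), abs=1e-6)

    def test_ou_five_fix_hand_track(self, make_track):
        # tiny hand-written track against the direct MVN density
        t = np.array([0.0, 7.0, 9.0, 20.0, 31.0])
        tr = make_track(t, [1.0, 2.0, -1.0, 0.5, 3.0], [0.0, -2.0, 1.0, 1.5, -0.5])
        cov = ou_cov(t, 4.0, 10.0)
        ll = ctmm.log_likelihood(tr, "OU", sigma2=4.0, tau_p=10.0, error_var=0.0, mu=(0.0, 0.0))
        assert ll == pytest.approx(dense_loglik(tr, cov, (0.0, 0.0)), abs=1e-6)

    def test_iou_step_matrices_match_van_loan(self):
        tau_v, s = 20.0, 4.0
        dts = np.array([0.5, 7.3, 31.0])
        F, Q = ctmm._step_matrices("IOU", dts, s, None, tau_v)
        A = np.array([[0.0, 1.0], [0.0, -1.0 / tau_v]])
        q = 2.0 * s / tau_v
        for i, d in enumerate(dts):
            M = np.zeros((4, 4))
            M[:2, :2] = A
            M[1, 3] = q
            M[2:, 2:] = -A.T
            E = expm(M * d)
            F_vl = E[:2, :2]
            Q_vl = E[:2, 2:] @ F_vl.T
            np.testing.assert_allclose(F[i], F_vl, atol=1e-12)
            np.testing.assert_allclose(Q[i], Q_vl, rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# fitting


class TestFit:
    def test_iid_closed_form(self, make_track):
        rng = np.random.default_rng(4)
        x = rng.normal(12.0, 3.0, 200)
        y = rng.normal(-7.0, 3.0, 200)
        m = ctmm.fit_movement_model(make_track(np.arange(200.0) * 10, x, y), "IID")
        assert m.mu[0] == pytest.approx(x.mean(), abs=1e-9)
        assert m.mu[1] == pytest.approx(y.mean(), abs=1e-9)
        ml_var = 0.5 * (np.var(x) + np.var(y))
        assert m.sigma2 == pytest.approx(ml_var, rel=1e-6)
        # closed-form Gaussian log-density
        expected = -0.5 * (
            2 * 200 * np.log(2 * np.pi * ml_var)
            + (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / ml_var
        )
        assert m.loglik == pytest.approx(expected, abs=1e-6)
        assert m.aic == pytest.approx(2 * 3 - 2 * m.loglik)

    def test_insufficient_data(self, make_track):
        tr = make_track(np.arange(5.0), np.zeros(5) + np.arange(5), np.zeros(5))
        with pytest.raises(InsufficientDataError):
            ctmm.fit_movement_model(tr, "OU")

    def test_ou_parameter_recovery(self):
        tr = simulate_family_track("OU", n=2000, dt_min=10.0, seed=99,
                                   sigma2=1e4, tau_p=60.0, mu=(500.0, 300.0))
        m = ctmm.fit_movement_model(tr, "OU")
        assert abs(m.tau_p - 60.0) / 60.0 < 0.25
        assert m.sigma2 == pytest.approx(1e4, rel=0.35)

    def test_nesting_never_decreases_loglik(self):
        tr = simulate_family_track("OU", n=300, dt_min=10.0, seed=3,
                                   sigma2=5e3, tau_p=45.0)
        iid = ctmm.fit_movement_model(tr, "IID")
        ou = ctmm.fit_movement_model(tr, "OU")
        ouf = ctmm.fit_movement_model(tr, "OUF")
        assert ou.loglik >= iid.loglik - 1e-6
        assert ouf.loglik >= ou.loglik - 1e-6


class TestSelect:
    def test_white_noise_selects_iid(self, make_track):
        rng = np.random.default_rng(8)
        tr = make_track(np.arange(400.0) * 10, rng.normal(0, 30, 400), rng.normal(0, 30, 400))
        assert ctmm.select_movement_model(tr).family == "IID"

    def test_single_family_returned(self):
        tr = simulate_family_track("OU", n=200, dt_min=10.0, seed=5, sigma2=1e4, tau_p=60.0)
        m = ctmm.select_movement_model(tr, families=("OU",))
        assert m.family == "OU"

    def test_all_failures_raise(self, make_track):
        tr = make_track(np.arange(5.0), np.arange(5.0), np.zeros(5))
        with pytest.raises(FitFailureError):
            ctmm.select_movement_model(tr)  # under the 10-fix minimum


# ---------------------------------------------------------------------------
# interpolation


class TestInterpolate:
    def _ou_model(self, **kw):
        d = dict(family="OU", mu=(0.0, 0.0), sigma2=1e4, tau_p=60.0, tau_v=None,
                 error_var=0.0, loglik=-1.0, k=4, aic=10.0, n=10)
        d.update(kw)
        return ctmm.MovementModel(**d)

    def test_exact_through_observations(self, make_track):
        rng = np.random.default_rng(21)
        tr = make_track(np.arange(0, 100, 10.0), rng.normal(0, 80, 10), rng.normal(0, 80, 10))
        it = ctmm.interpolate(tr, self._ou_model(n=10), interval_min=5.0)
        idx = np.searchsorted(it.times.astype("int64"), tr.times.astype("int64"))
        np.testing.assert_allclose(it.x[idx], tr.x, atol=1e-9)
        np.testing.assert_allclose(it.y[idx], tr.y, atol=1e-9)
        assert it.regular and it.interval_min == 5.0

    def test_iid_returns_mu_between_fixes(self, make_track):
        rng = np.random.default_rng(22)
        tr = make_track(np.arange(0, 100, 10.0), rng.normal(7, 5, 10), rng.normal(9, 5, 10))
        model = ctmm.MovementModel(family="IID", mu=(7.0, 9.0), sigma2=25.0, tau_p=None,
                                   tau_v=None, error_var=0.0, loglik=-1.0, k=3, aic=8.0, n=10)
        it = ctmm.interpolate(tr, model, interval_min=5.0)
        off = ~np.isin(it.times, tr.times)
        assert off.any()
        np.testing.assert_allclose(it.x[off], 7.0)
        np.testing.assert_allclose(it.y[off], 9.0)

    def test_ou_two_fix_midpoint_matches_kriging(self, make_track):
        tr = make_track([0.0, 30.0], [100.0, 200.0], [-50.0, 10.0])
        model = self._ou_model(mu=(20.0, 30.0), sigma2=5e3, tau_p=45.0, n=2)
        it = ctmm.interpolate(tr, model, interval_min=15.0)
        assert len(it) == 3

        def krig(obs, mu):
            c = 5e3 * np.exp(-15.0 / 45.0)
            C = 5e3 * np.array([[1.0, np.exp(-30.0 / 45.0)], [np.exp(-30.0 / 45.0), 1.0]])
            w = np.linalg.solve(C, np.array([c, c]))
            return mu + w @ (np.array(obs) - mu)

        assert it.x[1] == pytest.approx(krig([100.0, 200.0], 20.0), rel=1e-8)
        assert it.y[1] == pytest.approx(krig([-50.0, 10.0], 30.0), rel=1e-8)

    def test_idempotent_on_regular_track(self, make_track):
        rng = np.random.default_rng(23)
        t = np.arange(0, 500, 5.0)
        tr = make_track(t, rng.normal(0, 60, len(t)), rng.normal(0, 60, len(t)))
        m = ctmm.fit_movement_model(tr, "OU")
        it = ctmm.interpolate(tr, m, interval_min=5.0)
        assert len(it) == len(tr)
        np.testing.assert_allclose(it.x, tr.x, atol=1e-8)
        np.testing.assert_allclose(it.y, tr.y, atol=1e-8)

    def test_empty_grid_rejected(self, make_track):
        # no 5-min grid point falls inside [1, 3] minutes
        tr = make_track([1.0, 3.0], [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(InsufficientDataError):
            ctmm.interpolate(tr, self._ou_model(n=2), interval_min=5.0)


def test_model_json_roundtrip(tmp_path):
    tr = simulate_family_track("OU", n=100, dt_min=10.0, seed=6, sigma2=1e4, tau_p=60.0)
    m = ctmm.fit_movement_model(tr, "OU")
    m.save(tmp_path / "m.json")
    back = ctmm.MovementModel.load(tmp_path / "m.json")
    assert back == m
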