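import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
import shapely

from contactrsf import rsf
from contactrsf.errors import DegenerateInputError, InsufficientDataError, InvalidArgumentError
from contactrsf.homerange import kde_homerange
from contactrsf.rsf import (
    PopulationRSF,
    RSFModel,
    UseAvailableDataset,
    aggregate_population,
    build_individual_dataset,
    crossvalidate,
    fit_rsf,
    predict_surface,
    screen_collinearity,
    select_model,
)


def synthetic_dataset(n_used, beta, rng, ratio=10, owner="o", binary=False):
    """Logistic design with one covariate of known effect (per SD)."""
    n_avail = ratio * n_used
    n = n_used + n_avail
    if binary:
        z = (rng.random(n) < 0.3).astype(float)
    else:
        z = rng.standard_normal(n)
    # accept/reject shaping: label by logistic prob conditional on z
    eta = beta * z
    p = 1 / (1 + np.exp(-(eta - math.log(ratio))))
    used = np.zeros(n, dtype=int)
    # fix label counts approximately by sampling Bernoulli
    used = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(
        {
            "used": used,
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "date": np.repeat(np.datetime64("2020-01-01"), n),
            "z": z,
        }
    )
    return UseAvailableDataset(owner=owner, data=df, covariates=["z"],
                               standardizers={}, ratio=10**9)


@pytest.fixture(scope="module")
def setup(tiny_env):
    rng = np.random.default_rng(3)
    from tests.conftest import track_from_minutes

    n = 100
    minutes = np.arange(n) * 5.0
    tr = track_from_minutes(
        minutes,
        rng.normal(300, 60, n).clip(20, 580),
        rng.normal(300, 60, n).clip(20, 580),
        animal_id="a",
        regular=True,
        interval_min=5.0,
    )
    hr = kde_homerange(np.column_stack([tr.x, tr.y]), tiny_env.grid,
                       isopleth_levels=(0.50, 0.95))
    return tr, hr


class TestBuildIndividualDataset:

    def test_thirty_available_per_used(self, setup, tiny_env):
        tr, hr = setup
        ds = build_individual_dataset(tr, hr, tiny_env, ratio=30, seed=11)
        assert ds.n_used == 100
        assert ds.n_available == 3000

    def test_available_inside_polygon(self, setup, tiny_env):
        tr, hr = setup
        ds = build_individual_dataset(tr, hr, tiny_env, ratio=30, seed=11)
        avail = ds.data[ds.data.used == 0]
        inside = shapely.contains_xy(hr.polygon(0.95), avail.x.to_numpy(), avail.y.to_numpy())
        assert inside.all()

    def test_seed_determinism(self, setup, tiny_env):
        tr, hr = setup
        d1 = build_individual_dataset(tr, hr, tiny_env, ratio=30, seed=42)
        d2 = build_individual_dataset(tr, hr, tiny_env, ratio=30, seed=42)
        pd.testing.assert_frame_equal(d1.data, d2.data)

    def test_available_inherit_paired_date(self, setup, tiny_env):
        tr, hr = setup
        ds = build_individual_dataset(tr, hr, tiny_env, ratio=30, seed=1)
        used_dates = ds.data[ds.data.used == 1]["date"].to_numpy()
        avail_dates = ds.data[ds.data.used == 0]["date"].to_numpy()
        np.testing.assert_array_equal(avail_dates, np.repeat(used_dates, 30))

    def test_standardized_continuous_covariates(self, setup, tiny_env):
        tr, hr = setup
        ds = build_individual_dataset(tr, hr, tiny_env, ratio=30, seed=2)
        for name in ds.standardizers:
            vals = ds.data[name]
            assert abs(vals.mean()) < 0.05
            assert 0.95 <= vals.std() <= 1.05
        # binary layers untouched
        assert set(np.unique(ds.data["road"])) <= {0.0, 1.0}


class TestScreenCollinearity:
    def test_duplicate_covariate_dropped(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(500)
        df = pd.DataFrame({"a": z, "b": z.copy(), "c": rng.standard_normal(500)})
        assert screen_collinearity(df) == ["a", "c"]

    def test_below_threshold_all_retained(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(2000)
        w = rng.standard_normal(2000)
        z = (z - z.mean()) / z.std()
        w = (w - (z @ w / len(w)) * z / 1.0)  # orthogonalize roughly
        w = (w - w.mean()) / w.std()
        b = 0.59 * z + math.sqrt(1 - 0.59**2) * w
        df = pd.DataFrame({"a": z, "b": b})
        assert abs(np.corrcoef(df.a, df.b)[0, 1]) < 0.6
        assert screen_collinearity(df) == ["a", "b"]

    def test_three_mutually_correlated_leave_one(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(1000)
        df = pd.DataFrame(
            {
                "a": z + rng.normal(0, 0.3, 1000),
                "b": z + rng.normal(0, 0.3, 1000),
                "c": z + rng.normal(0, 0.3, 1000),
            }
        )
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        assert (np.abs(corr[np.triu_indices(3, 1)]) > 0.8).all()
        assert screen_collinearity(df) == ["a"]

    def test_priority_order_controls_drop(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(500)
        df = pd.DataFrame({"a": z, "b": z.copy()})
        assert screen_collinearity(df, priority_order=["b", "a"]) == ["b"]


class TestFitRSF:
    def test_null_covariate_not_significant(self):
        rng = np.random.default_rng(10)
        ds = synthetic_dataset(600, 0.0, rng)
        m = fit_rsf(ds, ["z"])
        assert abs(m.coef["z"]) < 3 * m.se["z"]

    def test_recovers_unit_log_odds(self):
        rng = np.random.default_rng(11)
        ds = synthetic_dataset(5000, 1.0, rng)
        m = fit_rsf(ds, ["z"])
        assert 0.8 <= m.coef["z"] <= 1.2

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(12)
        ds = synthetic_dataset(500, 0.5, rng)
        y = ds.data["used"].to_numpy()
        p = y.mean()
        expected = len(y) * (p * math.log(p) + (1 - p) * math.log(1 - p))
        # closed form vs a fit on a constant pseudo-covariate
        b0, ll = rsf.fit_intercept_only(ds)
        assert ll == pytest.approx(expected, rel=1e-12)
        assert b0 == pytest.approx(math.log(p / (1 - p)))

    def test_missing_label_class_rejected(self):
        df = pd.DataFrame(
            {"used": np.ones(50, dtype=int), "x": 0.0, "y": 0.0,
             "date": np.datetime64("2020-01-01"), "z": np.random.default_rng(0).standard_normal(50)}
        )
        ds = UseAvailableDataset(owner="o", data=df, covariates=["z"], standardizers={}, ratio=30)
        with pytest.raises(InvalidArgumentError):
            fit_rsf(ds, ["z"])

    def test_separation_triggers_ridge(self):
        rng = np.random.default_rng(13)
        n = 200
        z = np.concatenate([np.ones(20), np.zeros(n - 20)])
        used = np.concatenate([np.ones(20, dtype=int), np.zeros(n - 20, dtype=int)])
        df = pd.DataFrame({"used": used, "x": 0.0, "y": 0.0,
                           "date": np.datetime64("2020-01-01"), "z": z})
        ds = UseAvailableDataset(owner="o", data=df, covariates=["z"], standardizers={}, ratio=30)
        m = fit_rsf(ds, ["z"])
        assert m.penalized
        assert np.isfinite(m.coef["z"])

    def test_aic_identity(self):
        rng = np.random.default_rng(14)
        m = fit_rsf(synthetic_dataset(400, 0.7, rng), ["z"])
        assert m.aic == pytest.approx(2 * m.k - 2 * m.loglik)


class TestSelectModel:
    def _owner_datasets(self, n_owners, n_used, seed):
        out = []
        for i in range(n_owners):
            rng = np.random.default_rng(seed + i)
            ds = synthetic_dataset(n_used, 1.0, rng, owner=f"o{i}")
            for j in range(3):
                ds.data[f"noise{j}"] = rng.standard_normal(len(ds.data))
            ds.covariates = ["z", "noise0", "noise1", "noise2"]
            out.append(ds)
        return out

    def test_single_candidate(self):
        datasets = self._owner_datasets(2, 300, 0)
        top, table = select_model([["z"]], datasets)
        assert top == ["z"]
        assert len(table) == 1

    def test_generating_model_beats_noise_superset(self):
        datasets = self._owner_datasets(5, 5000, 100)
        top, table = select_model([["z"], ["z", "noise0", "noise1", "noise2"]], datasets)
        assert top == ["z"]

    def test_tie_prefers_fewer_parameters(self, monkeypatch):
        datasets = self._owner_datasets(2, 200, 5)
        calls = {}

        def fake_fit(ds, formula):
            m = fit_rsf(ds, ["z"])
            object.__setattr__  # no-op
            m.formula = list(formula)
            return m

        monkeypatch.setattr(rsf, "fit_rsf", fake_fit)
        top, table = select_model([["z", "noise0"], ["z"]], datasets)
        assert top == ["z"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_model([], self._owner_datasets(1, 100, 0))

    def test_single_owner_reduces_to_aic(self):
        ds = self._owner_datasets(1, 2000, 7)
        top, table = select_model([["z"], ["noise0"]], ds)
        m_z = fit_rsf(ds[0], ["z"])
        m_n = fit_rsf(ds[0], ["noise0"])
        assert table.aic.tolist() == pytest.approx([m_z.aic, m_n.aic])
        assert top == ["z"]


def _model(owner, beta, se=0.1, n_used=100):
    return RSFModel(
        owner=owner, formula=["z"], coef={"intercept": 0.0, "z": beta},
        se={"intercept": 0.1, "z": se}, loglik=-10.0, k=2, aic=2 * 2 + 20.0,
        n_used=n_used, n_available=n_used * 30,
    )


class TestAggregate:
    def test_equal_weights_arithmetic_mean(self):
        pop = aggregate_population(
            [_model("a", 1.0), _model("b", 3.0)],
            owner_pair_counts={"a": 1, "b": 1},
            owner_sample_sizes={"a": 10, "b": 10},
        )
        assert pop.beta[0] == pytest.approx(2.0)

    def test_degenerate_single_owner(self):
        pop = aggregate_population([_model("a", 1.5)])
        assert pop.beta[0] == pytest.approx(1.5)
        assert pop.weights == {"a": 1.0}

    def test_weighted_mean_arithmetic(self):
        pop = aggregate_population(
            [_model("a", 1.0), _model("b", 2.0), _model("c", 3.0)],
            owner_pair_counts={"a": 1, "b": 1, "c": 1},
            owner_sample_sizes={"a": 0.5, "b": 0.3, "c": 0.2},
        )
        assert pop.beta[0] == pytest.approx(1.7)
        # SE of the weighted mean
        assert pop.se[0] == pytest.approx(np.sqrt((0.5**2 + 0.3**2 + 0.2**2) * 0.1**2))

    def test_containment_invariant(self):
        pop = aggregate_population([_model("a", -2.0), _model("b", 5.0)])
        assert -2.0 <= pop.beta[0] <= 5.0

    def test_mismatched_formulas_rejected(self):
        m2 = _model("b", 1.0)
        m2.formula = ["w"]
        m2.coef = {"intercept": 0.0, "w": 1.0}
        m2.se = {"intercept": 0.1, "w": 0.1}
        with pytest.raises(InvalidArgumentError):
            aggregate_population([_model("a", 1.0), m2])


class TestCrossValidate:
    def test_fold_sizes_withhold_20_percent(self):
        rng = np.random.default_rng(20)
        ds = synthetic_dataset(1000, 1.0, rng)
        n_used = ds.n_used
        cv = crossvalidate(ds, ["z"], k=5, n_bins=10, seed=0)
        assert len(cv.fold_rs) == 5
        # fold sizes are n_used/5 within 1
        sizes = [len(f) for f in np.array_split(np.arange(n_used), 5)]
        assert max(sizes) - min(sizes) <= 1

    def test_informative_covariate_high_rs(self):
        rng = np.random.default_rng(21)
        ds = synthetic_dataset(4000, 2.5, rng)
        cv = crossvalidate(ds, ["z"], k=5, n_bins=10, seed=1)
        assert cv.mean_rs > 0.9

    def test_shuffled_labels_near_zero(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            ds = synthetic_dataset(400, 1.2, rng, ratio=8)
            shuffled = ds.data["used"].sample(frac=1.0, random_state=seed).to_numpy()
            ds.data["used"] = shuffled
            cv = crossvalidate(ds, ["z"], k=5, n_bins=10, seed=seed)
            means.append(cv.mean_rs)
        assert abs(np.nanmean(means)) < 0.35

    def test_too_few_used_points(self):
        rng = np.random.default_rng(22)
        ds = synthetic_dataset(3, 0.0, rng)
        with pytest.raises(InsufficientDataError):
            crossvalidate(ds, ["z"], k=5)


class TestPredictSurface:
    def _pop(self, names, beta):
        b = np.asarray(beta, dtype=float)
        return PopulationRSF(
            covariates=list(names), beta=b, se=np.full(len(b), 0.1),
            ci_low=b - 0.2, ci_high=b + 0.2, weights={"a": 1.0}, n_owners=1,
        )

    def test_zero_coefficients_uniform(self, tiny_env):
        s = predict_surface(self._pop(["road"], [0.0]), tiny_env, dt.date(2020, 1, 1), {})
        assert np.ptp(s) == 0.0

    def test_binary_two_level_surface(self, tiny_env):
        s = predict_surface(self._pop(["road"], [1.5]), tiny_env, dt.date(2020, 1, 1), {})
        road = tiny_env.static["road"]
        assert np.all(s[road == 1] == 1.0)
        assert np.all(s[road == 0] == 0.0)

    def test_rescale_exact_bounds(self, tiny_env):
        s = predict_surface(
            self._pop(["tree_canopy"], [0.8]), tiny_env, dt.date(2020, 1, 1),
            {"tree_canopy": (0.5, 0.2)},
        )
        assert s.min() == 0.0 and s.max() == 1.0

    def test_standardization_equivariance(self, tiny_env):
        # rescaled surfaces agree whether or not the covariate is standardized
        day = dt.date(2020, 1, 1)
        raw = predict_surface(self._pop(["tree_canopy"], [0.8]), tiny_env, day, {})
        sd = float(tiny_env.static["tree_canopy"].std())
        mean = float(tiny_env.static["tree_canopy"].mean())
        std = predict_surface(
            self._pop(["tree_canopy"], [0.8 * sd]), tiny_env, day, {"tree_canopy": (mean, sd)},
        )
        np.testing.assert_allclose(raw, std, atol=1e-6)
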