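import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snowcross import (
    CountDataset,
    CountModelSpec,
    FittedCountModel,
    average_models,
    compare_approaches,
    exhaustive_search,
    filter_candidates,
    fit,
    iterative_search,
    lr_test,
    pick_distribution,
    summed_importance,
    vuong_test,
)
from snowcross.selection import CandidateModelSet, SearchConfig, akaike_weights


def poisson_dataset(seed, n=400, effects=None, n_predictors=6, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"x{i}" for i in range(n_predictors)]
    X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    eta = np.full(n, 0.3)
    for name, b in (effects or {}).items():
        eta = eta + b * X[name].to_numpy()
    return CountDataset(rng.poisson(np.exp(eta)), X)


def fake_model(
    family="poisson",
    predictors=(),
    ll=-100.0,
    n=400,
    p=None,
    se=None,
    est=None,
):
    """Hand-built FittedCountModel for filter/averaging unit tests."""
    zero = () if family in ("zip", "zinb") else None
    spec = CountModelSpec(family, tuple(predictors), zero)
    count_coef = {"intercept": 0.1}
    count_se = {"intercept": 0.05}
    count_p = {"intercept": 0.5}
    for name in predictors:
        count_coef[name] = (est or {}).get(name, 0.5)
        count_se[name] = (se or {}).get(name, 0.1)
        count_p[name] = (p or {}).get(name, 0.01)
    zero_coef = {"intercept": -1.0} if zero is not None else {}
    zero_se = {"intercept": 0.3} if zero is not None else {}
    zero_p = {"intercept": 0.01} if zero is not None else {}
    return FittedCountModel(
        spec=spec,
        params=np.zeros(spec.df),
        count_coef=count_coef,
        zero_coef=zero_coef,
        theta=1.0 if family in ("negbin", "zinb") else None,
        count_se=count_se,
        zero_se=zero_se,
        theta_se=None,
        count_p=count_p,
        zero_p=zero_p,
        log_likelihood=ll,
        df=spec.df,
        n=n,
        converged=True,
    )


class TestLrTest:
    def test_deer_transect_printed_values(self):
        res = lr_test(-944.375, -681.014, 1)
        assert res["statistic"] == pytest.approx(526.72, abs=0.005)
        assert res["p"] < 1e-15

    def test_elk_highway_printed_values(self):
        res = lr_test(-975.888, -649.758, 1)
        assert res["statistic"] == pytest.approx(652.26, abs=0.005)

    def test_identical_likelihoods(self):
        res = lr_test(-50.0, -50.0, 1)
        assert res["statistic"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_inverted_likelihoods_warn_and_clamp(self):
        res = lr_test(-49.0, -50.0, 1)
        assert res["statistic"] == 0.0 and res["warning"]

    def test_df_validated(self):
        with pytest.raises(ValueError):
            lr_test(-50.0, -49.0, 0)


@pytest.fixture(scope="module")
def fitted_pair(zip_dataset):
    m_zip = fit(CountModelSpec("zip", (), ()), zip_dataset)
    m_pois = fit(CountModelSpec("poisson", ()), zip_dataset)
    return m_zip, m_pois


class TestVuong:
    def test_identical_models_undefined(self, fitted_pair, zip_dataset):
        m_zip, _ = fitted_pair
        res = vuong_test(m_zip, m_zip, zip_dataset)
        assert res.undefined and res.preference == "undefined"

    def test_zip_preferred_on_zip_data(self, fitted_pair, zip_dataset):
        m_zip, m_pois = fitted_pair
        res = vuong_test(m_zip, m_pois, zip_dataset)
        assert res.V > 1.96 and res.preference == "model1"

    def test_loop_oracle_agreement(self, fitted_pair, zip_dataset):
        m_zip, m_pois = fitted_pair
        res = vuong_test(m_zip, m_pois, zip_dataset)
        # independent per-observation loop
        y = zip_dataset.counts
        m = []
        for i in range(len(y)):
            row = zip_dataset.predictors.iloc[[i]]
            p1 = float(m_zip.pmf(np.array([y[i]]), row)[0])
            p2 = float(m_pois.pmf(np.array([y[i]]), row)[0])
            m.append(math.log(p1) - math.log(p2))
        m = np.asarray(m)
        V = math.sqrt(len(m)) * m.mean() / m.std(ddof=1)
        assert res.V == pytest.approx(V, abs=1e-10)

    def test_mismatched_observations_rejected(self, fitted_pair):
        m_zip, m_pois = fitted_pair
        other = poisson_dataset(0, n=10)
        with pytest.raises(ValueError):
            vuong_test(m_zip, m_pois, other)


class TestPickDistribution:
    def test_carnivores_highway_printed_values_pick_zip(self):
        fits = {
            "poisson": fake_model("poisson", ll=-204.677),
            "negbin": fake_model("negbin", ll=-203.204),
            "zip": fake_model("zip", ll=-202.762),
            "zinb": fake_model("zinb", ll=-202.762),
        }
        report = pick_distribution(fits)
        assert report["family"] == "zip"
        assert report["partial"]  # no data table -> Vuong unavailable

    def test_moose_transect_printed_values_pick_poisson(self):
        fits = {
            "poisson": fake_model("poisson", ll=-162.046),
            "negbin": fake_model("negbin", ll=-161.542),
            "zip": fake_model("zip", ll=-161.253),
            "zinb": fake_model("zinb", ll=-161.253),
        }
        report = pick_distribution(fits)
        assert report["family"] == "poisson"

    def test_exact_tie_picks_simplest_with_flag(self):
        # equal AIC requires ll differences matching df differences
        fits = {
            "poisson": fake_model("poisson", ll=-100.0),  # df 1 -> AIC 202
            "negbin": fake_model("negbin", ll=-99.0),  # df 2 -> AIC 202
            "zip": fake_model("zip", ll=-99.0),  # df 2 -> AIC 202
            "zinb": fake_model("zinb", ll=-98.0),  # df 3 -> AIC 202
        }
        report = pick_distribution(fits)
        assert report["family"] == "poisson" and report["tie"]

    def test_full_report_on_real_fits(self, zip_dataset):
        fits = {}
        for family, zero in (
            ("poisson", None),
            ("negbin", None),
            ("zip", ()),
            ("zinb", ()),
        ):
            fits[family] = fit(CountModelSpec(family, (), zero), zip_dataset)
        report = pick_distribution(fits, zip_dataset)
        assert not report["partial"]
        assert report["family"] in {"zip", "zinb"}
        assert "poisson_vs_zip" in report["vuong"]
        assert report["justification"]


class TestIterativeSearch:
    def test_empty_pool_returns_intercept_only(self):
        ds = poisson_dataset(0)
        result = iterative_search(ds, "poisson", [])
        assert len(result.models) == 1
        assert result.best.spec.count_predictors == ()

    def test_branching_retains_near_ties(self):
        # two predictors with similar effects: both one-predictor models fall
        # within the retention delta, so the two-predictor model must be reached
        ds = poisson_dataset(3, n=600, effects={"x0": 0.4, "x1": 0.4}, n_predictors=4)
        result = iterative_search(ds, "poisson", [f"x{i}" for i in range(4)])
        sets = {tuple(sorted(m.spec.count_predictors)) for m in result.models}
        assert ("x0", "x1") in sets

    def test_useless_pool_stops_immediately(self):
        ds = poisson_dataset(4, n=500, effects={}, n_predictors=3)
        result = iterative_search(ds, "poisson", ["x0", "x1", "x2"])
        assert result.best.spec.count_predictors == ()

    def test_best_never_worse_than_intercept_only(self):
        ds = poisson_dataset(5, n=300, effects={"x0": 0.5})
        result = iterative_search(ds, "poisson", [f"x{i}" for i in range(6)])
        intercept_aicc = next(
            m for m in result.models if m.spec.count_predictors == ()
        ).aicc()
        assert result.best_criterion <= intercept_aicc

    def test_matches_exhaustive_on_small_pool(self):
        hits = 0
        for seed in range(5):
            ds = poisson_dataset(seed, n=300, effects={"x0": 0.5, "x1": -0.4}, n_predictors=5)
            pool = [f"x{i}" for i in range(5)]
            beam = iterative_search(ds, "poisson", pool)
            exact = exhaustive_search(ds, "poisson", pool)
            assert beam.best_criterion >= exact.best_criterion - 1e-6
            if beam.best_criterion <= exact.best_criterion + 1e-6:
                hits += 1
        assert hits >= 4

    def test_trace_records_every_fit(self):
        ds = poisson_dataset(6, n=200, effects={"x0": 0.6}, n_predictors=3)
        result = iterative_search(ds, "poisson", ["x0", "x1", "x2"])
        assert len(result.trace) >= len(result.models)
        assert all("aicc" in entry for entry in result.trace)


class TestFilterCandidates:
    def make_set(self, models):
        return CandidateModelSet(approach="combined", family="poisson", models=models)

    def test_high_p_removed(self):
        bad = fake_model(predictors=("a",), p={"a": 0.20})
        result = filter_candidates(self.make_set([bad]))
        assert not result.models
        assert "p>0.15" in result.filter_log[0]["reason"]

    def test_large_se_removed(self):
        bad = fake_model(predictors=("a",), se={"a": 60.0})
        result = filter_candidates(self.make_set([bad]))
        assert not result.models
        assert "SE>50" in result.filter_log[0]["reason"]

    def test_large_estimate_removed(self):
        bad = fake_model(predictors=("a",), est={"a": 80.0})
        result = filter_candidates(self.make_set([bad]))
        assert "|estimate|>50" in result.filter_log[0]["reason"]

    def test_compliant_set_unchanged(self):
        good = [fake_model(), fake_model(predictors=("a",), p={"a": 0.01})]
        result = filter_candidates(self.make_set(good))
        assert len(result.models) == 2 and not result.filter_log

    def test_intercept_p_exempt(self):
        model = fake_model()
        model.count_p["intercept"] = 0.9
        result = filter_candidates(self.make_set([model]))
        assert result.models


class TestAverageModels:
    def make_set(self, models):
        return CandidateModelSet(approach="combined", family="poisson", models=models)

    def test_single_model_gets_weight_one(self):
        model = fake_model(ll=-100.0)
        avg = average_models(self.make_set([model]))
        assert avg.weights.tolist() == [1.0]
        table = pd.DataFrame({"x": [0.0]})
        assert np.allclose(avg.predict(table), model.predict_mean(table))

    def test_delta_two_weights(self):
        # AICc gap of exactly 2: ll difference of 1 at equal df won't do;
        # use two specs of equal df with ll gap 1
        m1 = fake_model(predictors=("a",), ll=-100.0)
        m2 = fake_model(predictors=("b",), ll=-101.0)
        avg = average_models(self.make_set([m1, m2]))
        w1 = 1 / (1 + math.exp(-1))
        assert avg.weights.tolist() == pytest.approx([w1, 1 - w1], abs=1e-9)
        assert avg.weights.tolist() == pytest.approx([0.731, 0.269], abs=1e-3)

    def test_member_beyond_delta_excluded(self):
        m1 = fake_model(predictors=("a",), ll=-100.0)
        m2 = fake_model(predictors=("b",), ll=-101.25)  # delta 2.5
        avg = average_models(self.make_set([m1, m2]))
        assert len(avg.members) == 1

    def test_absent_predictor_contributes_zero(self):
        m1 = fake_model(predictors=("a",), ll=-100.0, est={"a": 1.0})
        m2 = fake_model(predictors=("b",), ll=-100.0, est={"b": 1.0})
        avg = average_models(self.make_set([m1, m2]))
        table = avg.coefficient_table().set_index("name")
        assert table.loc["a", "estimate"] == pytest.approx(0.5)
        assert table.loc["b", "estimate"] == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_models(self.make_set([]))

    @given(st.floats(min_value=-1e6, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_akaike_weights_offset_invariant(self, offset):
        base = np.array([100.0, 101.5, 103.0])
        assert np.allclose(akaike_weights(base), akaike_weights(base + offset))


class TestCompareApproaches:
    def test_identical_values_tied(self):
        results = {("200m", "poisson"): 100.0, ("500m", "poisson"): 100.0}
        comparison = compare_approaches(results)
        assert comparison.ties

    def test_best_remote_excludes_digitized(self):
        results = {
            ("digitized", "poisson"): 90.0,
            ("200m", "poisson"): 95.0,
            ("combined", "poisson"): 85.0,
        }
        comparison = compare_approaches(results)
        assert comparison.overall_best == ("combined", "poisson")
        assert comparison.best_remote == ("200m", "poisson")

    def test_planted_scale_recovered(self):
        # truth lives on the 500 m variants: the 500 m approach should win
        # a majority of seeds against the 200 m and 1 km approaches
        names = [f"v{i}_{s}m" for s in (200, 500, 1000) for i in range(4)]
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            latent = rng.standard_normal((400, 4))
            cols = {}
            for s in (200, 500, 1000):
                for i in range(4):
                    cols[f"v{i}_{s}m"] = (
                        0.8 * latent[:, i] + 0.6 * rng.standard_normal(400)
                    )
            X = pd.DataFrame(cols)
            eta = 0.2 + 0.6 * X["v0_500m"] - 0.5 * X["v1_500m"]
            ds = CountDataset(rng.poisson(np.exp(eta)), X)
            best = {}
            for approach, scale in (("200m", 200), ("500m", 500), ("1km", 1000)):
                pool = [f"v{i}_{scale}m" for i in range(4)]
                best[approach] = iterative_search(ds, "poisson", pool).best_criterion
            comparison = compare_approaches(
                {(a, "poisson"): v for a, v in best.items()}
            )
            if comparison.overall_best[0] == "500m":
                wins += 1
        assert wins > n_seeds / 2

    def test_summed_importance_table(self):
        m_hwy = fake_model(predictors=("water_500m",), est={"water_500m": 0.4})
        m_trans = fake_model(predictors=("water_200m",), est={"water_200m": -0.3})
        avg_h = average_models(
            CandidateModelSet(approach="3-scales", family="poisson", models=[m_hwy])
        )
        avg_t = average_models(
            CandidateModelSet(approach="3-scales", family="poisson", models=[m_trans])
        )
        table = summed_importance(
            {("highway", "deer"): avg_h, ("transect", "deer"): avg_t}
        )
        assert table.loc["water", "highway_positive"] == 1
        assert table.loc["water", "transect_negative"] == 1
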