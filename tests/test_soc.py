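"""SOC stocks, pedotransfer selection, zone imputation and cleaning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from farmsoc import SynthConfig, simulate
from farmsoc.soc import (benchmark_ratio, clean_records, compute_soc_metrics,
                         delta_soc, enumerate_bd_candidates, fit_bd_models,
                         impute_zone, predict_bd_ref, soc_stock)
from farmsoc.synth import noiseless


class TestSocStock:
    @pytest.mark.parametrize("bd, oc, cf, expected", [
        (1.0, 10.0, 0.0, 20.0),
        (1.3, 15.0, 0.1, 35.1),
        (1.5, 25.0, 1.0, 0.0),          # all-stone soil
    ])
    def test_known_values(self, bd, oc, cf, expected):
        assert soc_stock(bd, oc, cf) == pytest.approx(expected)

    @given(bd=st.floats(0.5, 2.0), oc=st.floats(0.1, 100), cf=st.floats(0, 0.9))
    @settings(max_examples=60, deadline=None)
    def test_linear_in_oc_and_fine_earth(self, bd, oc, cf):
        assert soc_stock(bd, 2 * oc, cf) == pytest.approx(2 * soc_stock(bd, oc, cf))
        assert soc_stock(bd, oc, cf) == pytest.approx(
            soc_stock(bd, oc, 0.0) * (1 - cf))
        assert soc_stock(bd + 0.1, oc, cf) > soc_stock(bd, oc, cf)


class TestBenchmarkRatio:
    def test_at_benchmark(self):
        assert benchmark_ratio(40.0, 40.0) == 1.0

    def test_above_benchmark(self):
        assert benchmark_ratio(60.0, 40.0) == pytest.approx(1.5)

    def test_zero_typical_rejected(self):
        with pytest.raises(ValueError):
            benchmark_ratio(60.0, 0.0)


class TestDeltaSoc:
    @pytest.mark.parametrize("oc0, oc1, expected", [
        (15.0, 15.0, 0.0),
        (15.0, 24.0, 1.0),
        (20.0, 11.0, -1.0),
    ])
    def test_known_values(self, oc0, oc1, expected):
        assert delta_soc(oc0, oc1, 2009, 2018) == pytest.approx(expected)

    def test_equal_years_rejected(self):
        with pytest.raises(ValueError):
            delta_soc(10.0, 12.0, 2018, 2018)


def _bd_frame(n=300, seed=5, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "land_use": "arable",
        "sand": rng.uniform(15, 85, n),
        "clay": rng.uniform(5, 45, n),
        "ph": rng.uniform(4.5, 8.2, n),
        "total_n": rng.uniform(0.5, 4.0, n),
        "map_mm": rng.uniform(400, 1200, n),
    })
    df["bd_measured"] = (1.6 - 0.02 * df["ph"] - 0.05 * df["total_n"]
                         - 5e-5 * df["sand"] * df["clay"]
                         + rng.normal(0, noise, n))
    return df


class TestBdModels:
    def test_candidate_enumeration_respects_hierarchy(self):
        cands = enumerate_bd_candidates()
        assert () in cands
        for terms in cands:
            if "sand:clay" in terms:
                assert "sand" in terms and "clay" in terms
        assert len(cands) == 40

    def test_noiseless_selection_recovers_generating_model(self):
        models = fit_bd_models(_bd_frame())
        m = models["arable"]
        # the interaction forces its main effects in; everything else out
        assert set(m.terms) == {"sand", "clay", "sand:clay", "total_n", "ph"}
        assert m.params["const"] == pytest.approx(1.6, abs=1e-6)
        assert m.params["ph"] == pytest.approx(-0.02, abs=1e-6)
        assert m.params["total_n"] == pytest.approx(-0.05, abs=1e-6)
        assert m.params["sand:clay"] == pytest.approx(-5e-5, abs=1e-6)
        assert m.params["sand"] == pytest.approx(0.0, abs=1e-6)
        assert m.params["clay"] == pytest.approx(0.0, abs=1e-6)

    def test_exact_tie_prefers_smaller_model(self):
        df = _bd_frame()
        df["bd_measured"] = 1.3            # constant: every model fits exactly
        models = fit_bd_models(df)
        assert models["arable"].terms == ()
        assert models["arable"].params["const"] == pytest.approx(1.3)

    def test_oc_candidate_rejected(self):
        with pytest.raises(ValueError, match="[Oo]rganic carbon"):
            fit_bd_models(_bd_frame(), candidate_terms=("ph", "oc_t1"))

    def test_insufficient_data_names_land_use(self):
        with pytest.raises(ValueError, match="arable"):
            fit_bd_models(_bd_frame(n=10))


class TestPredictBdRef:
    def test_intercept_only_constant(self):
        df = _bd_frame(n=60)
        df["bd_measured"] = 1.3
        models = fit_bd_models(df)
        pred = predict_bd_ref(df, models)
        assert np.allclose(pred, 1.3)

    def test_clipped_to_plausible_range(self):
        df = _bd_frame()
        models = fit_bd_models(df)
        extreme = df.head(2).copy()
        extreme[["sand", "clay"]] = 1e5       # drives the prediction negative
        pred = models["arable"].predict(extreme)
        assert (pred == 0.1).all()

    def test_missing_covariates_give_nan(self):
        df = _bd_frame()
        models = fit_bd_models(df)
        holey = df.head(3).copy()
        holey.loc[holey.index[0], "ph"] = np.nan
        pred = models["arable"].predict(holey)
        assert np.isnan(pred.iloc[0]) and pred.iloc[1:].notna().all()

    def test_recovers_generative_density(self):
        df = _bd_frame()
        models = fit_bd_models(df)
        pred = predict_bd_ref(df, models)
        assert np.allclose(pred, df["bd_measured"], atol=1e-6)


class TestImputeZone:
    def _points(self, n=120, seed=9):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "oc_t1": rng.uniform(5, 50, n),
            "region": rng.choice(["R01", "R02"], n),
            "land_cover": rng.choice(["wheat", "perm_grass"], n),
            "sand": rng.uniform(10, 90, n),
            "clay": rng.uniform(5, 45, n),
            "ph": rng.uniform(4, 8, n),
            "map_mm": rng.uniform(400, 1200, n),
            "altitude_m": rng.uniform(0, 900, n),
        })
        df["zone"] = np.where(df["sand"] >= 50, "sandy", "loamy")
        return df

    def test_separable_zones_recovered_exactly(self):
        df = self._points()
        truth = df["zone"].copy()
        df.loc[df.index[::4], "zone"] = None
        zones, oob = impute_zone(df, n_trees=100, seed=0)
        assert (zones == truth).all()
        assert oob < 0.05

    def test_permuted_labels_error_near_null_rate(self):
        df = self._points(n=400)
        rng = np.random.default_rng(1)
        df["zone"] = rng.permutation(df["zone"].to_numpy())
        _, oob = impute_zone(df, n_trees=200, seed=0)
        null = 1.0 - df["zone"].value_counts(normalize=True).max()
        assert oob == pytest.approx(null, abs=0.12)

    def test_single_class_training_predicts_that_class(self):
        df = self._points(n=40)
        df["zone"] = "loamy"
        df.loc[df.index[:10], "zone"] = None
        zones, _ = impute_zone(df, n_trees=20, seed=0)
        assert (zones == "loamy").all()

    def test_small_classes_rejected(self):
        df = self._points(n=30)
        df.loc[df.index[df["zone"] == "sandy"][3:], "zone"] = "loamy"
        if (df["zone"] == "sandy").sum() == 0:
            df.loc[df.index[:3], "zone"] = "sandy"
        with pytest.raises(ValueError, match="sandy"):
            impute_zone(df)


class TestCleaning:
    def _metrics(self):
        return pd.DataFrame({
            "oc_t0": [10.0, 10.0, 10.0, 170.0, 10.0, 10.0],
            "oc_t1": [12.0, 160.0, 161.0, 12.0, 21.0, 12.0],
            "land_use": ["arable"] * 6,
            "land_use_t0": ["arable"] * 5 + ["grassland"],
            "delta_soc": [2.0 / 9, 150.0 / 9, 151.0 / 9, -158.0 / 9,
                          11.0 / 9, 2.0 / 9],
        })

    def test_organic_threshold_is_strict(self):
        res = clean_records(self._metrics())
        assert not res.flags.loc[1, "removed_organic"]   # exactly 160 retained
        assert res.flags.loc[2, "removed_organic"]       # 161 removed

    def test_relative_change_filter(self):
        # 10 -> 21 g/kg over 9 years: 110% relative change, removed
        res = clean_records(self._metrics())
        assert res.flags.loc[4, "removed_delta_outlier"]
        assert not res.flags.loc[0, "removed_delta_outlier"]

    def test_land_use_change_removed_from_delta_set(self):
        res = clean_records(self._metrics())
        assert res.flags.loc[5, "removed_landuse_change"]
        assert 5 not in res.delta_set.index
        assert 5 in res.stock_set.index          # stocks keep the point

    def test_absolute_change_filter(self):
        m = self._metrics()
        m.loc[0, ["oc_t0", "oc_t1", "delta_soc"]] = [100.0, 128.0, 28.0 / 9]
        res = clean_records(m)
        assert res.flags.loc[0, "removed_delta_outlier"]   # 3.1 g/kg/yr

    def test_idempotent(self):
        res = clean_records(self._metrics())
        again = clean_records(res.delta_set)
        assert len(again.delta_set) == len(res.delta_set)
        assert again.counts["removed_delta_outlier"] == 0


class TestEndToEnd:
    def test_noiseless_pipeline_reproduces_true_stocks(self):
        cfg = noiseless(SynthConfig(seed=21, n_points=500,
                                    n_farms_per_region=80))
        sim = simulate(cfg)
        metrics, models, _ = compute_soc_metrics(sim.points, sim.benchmarks)
        gt = sim.ground_truth.points.set_index("point_id")
        got = metrics.set_index("point_id")["stock"]
        assert np.allclose(got, gt.loc[got.index, "stock_true"], atol=1e-6)

    def test_benchmark_ratios_centre_on_one(self, small_sim):
        metrics, _, clean = compute_soc_metrics(small_sim.points,
                                                small_sim.benchmarks,
                                                min_bd_points=8)
        by_zone = np.exp(np.log(clean.stock_set["benchmark_ratio"])
                         .groupby(clean.stock_set["zone"]).mean())
        assert by_zone.between(0.8, 1.25).all()
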