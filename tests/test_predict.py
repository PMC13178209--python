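"""Management prediction: weights, weighted statistics, tier matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from farmsoc.indicators import compute_indicators
from farmsoc.predict import (farm_weight, match_point, predict_at_points,
                             weighted_median, weighted_sd,
                             within_region_kw_test)


class TestFarmWeight:
    @pytest.mark.parametrize("area, uaa, total, expected", [
        (10.0, 10.0, 10.0, 1.0),              # monoculture single farm
        (10.0, 10.0, 40.0, 0.5),              # sqrt(1 x 0.25)
        (5.0, 10.0, 20.0, 0.3535533906),      # sqrt(0.5 x 0.25)
    ])
    def test_values(self, area, uaa, total, expected):
        assert farm_weight(area, uaa, total) == pytest.approx(expected)

    @pytest.mark.parametrize("area, uaa, total", [
        (1.0, 0.0, 10.0), (0.0, 5.0, 10.0), (1.0, 5.0, 0.0), (6.0, 5.0, 10.0),
    ])
    def test_invalid_inputs(self, area, uaa, total):
        with pytest.raises(ValueError):
            farm_weight(area, uaa, total)


class TestWeightedMedian:
    def test_heavy_weight_pulls_median(self):
        # brute-force check: m=3 minimises sum w|x-m| for weights {1,1,10}
        assert weighted_median([1.0, 2.0, 3.0], [1.0, 1.0, 10.0]) == 3.0

    def test_single_value(self):
        assert weighted_median([4.2], [0.5]) == 4.2
        assert weighted_sd([4.2], [0.5]) == 0.0

    def test_missing_dropped_pairwise(self):
        assert weighted_median([1.0, np.nan, 9.0], [1.0, 99.0, 1.0]) == 1.0

    def test_all_missing_gives_nan(self):
        assert np.isnan(weighted_median([np.nan], [1.0]))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_median([1.0, 2.0], [1.0, 0.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_equal_weights_reduce_to_lower_median(self, values):
        vals = sorted(values)
        lower = vals[(len(vals) - 1) // 2]
        got = weighted_median(values, np.ones(len(values)))
        assert got == lower

    def test_oracle_minimises_weighted_absolute_loss(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 9)
            v = rng.choice([0.0, 1.0, 2.0, 3.5, 7.0], n)
            w = rng.uniform(0.1, 5.0, n)
            loss = np.array([np.sum(w * np.abs(v - m)) for m in v])
            argmin = v[np.isclose(loss, loss.min(), rtol=1e-12)]
            assert weighted_median(v, w) == argmin.min()


class TestWeightedSd:
    def test_equal_weights_match_population_sd(self):
        v = np.array([1.0, 4.0, 4.0, 9.0])
        assert weighted_sd(v, np.ones(4)) == pytest.approx(np.std(v))

    def test_weight_scale_invariance(self):
        v = [1.0, 2.0, 5.0]
        assert weighted_sd(v, [1.0, 2.0, 3.0]) == pytest.approx(
            weighted_sd(v, [10.0, 20.0, 30.0]))


def _toy_farms(n, region="R01", alt="<300", crop="wheat", start=0):
    return pd.DataFrame({
        "farm_id": [f"T{start + i:04d}" for i in range(n)],
        "year": 2018, "region": region, "country": "C01",
        "altitude_m": 100.0, "altitude_class": alt, "farm_type": "arable",
        "size_class": "<20", "uaa_ha": 10.0, "organic": False,
        "livestock_units": 1.0, "mineral_n_kg": 500.0, "mineral_p_kg": 100.0,
        "mineral_k_kg": 200.0, f"area_{crop}": 10.0,
    })


def _centroids():
    return pd.DataFrame({"region": ["R01", "R02"], "country": ["C01", "C01"],
                         "lon": [0.0, 1.0], "lat": [45.0, 45.0]})


class TestMatchPoint:
    def _point(self, crop="wheat", alt="<300"):
        return {"region": "R01", "country": "C01", "altitude_class": alt,
                "land_cover": crop}

    def test_exactly_fifteen_farms_is_tier_one(self):
        farms = _toy_farms(15)
        ind = compute_indicators(farms)
        g = match_point(self._point(), farms, ind)
        assert g.tier == "1" and g.n_farms == 15

    def test_fourteen_falls_back_to_tier_two(self):
        farms = pd.concat([_toy_farms(14, alt="<300"),
                           _toy_farms(14, alt=">600", start=100)],
                          ignore_index=True).fillna(0.0)
        ind = compute_indicators(farms)
        g = match_point(self._point(), farms, ind)
        assert g.tier == "2" and g.n_farms == 28

    def test_no_same_crop_uses_tier_three_land_use(self):
        farms = _toy_farms(20, region="R02", crop="barley")
        ind = compute_indicators(farms)
        g = match_point(self._point(crop="wheat"), farms, ind,
                        region_centroids=_centroids())
        assert g.tier == "3" and g.n_farms == 20

    def test_unmatched_without_centroids(self):
        farms = _toy_farms(3)
        ind = compute_indicators(farms)
        g = match_point(self._point(), farms, ind)
        assert g.tier == "unmatched" and g.n_farms == 0

    def test_weights_match_formula(self):
        farms = _toy_farms(15)
        ind = compute_indicators(farms)
        g = match_point(self._point(), farms, ind)
        # identical farms: area=uaa=10, total=150
        assert np.allclose(g.weights, np.sqrt(1.0 * 10.0 / 150.0))


class TestPredictAtPoints:
    def _points(self, crop="wheat", n=4):
        return pd.DataFrame({
            "point_id": [f"P{i:03d}" for i in range(n)],
            "region": "R01", "country": "C01",
            "altitude_class": "<300", "land_cover": crop,
        })

    def test_identical_farms_give_their_value_sd_zero(self):
        farms = _toy_farms(20)
        ind = compute_indicators(farms)
        out = predict_at_points(self._points(), farms, ind)
        assert (out["tier"] == "1").all()
        assert out["n_input_med"].unique() == pytest.approx(
            500.0 / 10.0 + 0.1 * 135.0)
        assert out["n_input_sd"].to_numpy() == pytest.approx(0.0, abs=1e-10)

    def test_unmatched_point_is_all_missing(self):
        farms = _toy_farms(20)
        ind = compute_indicators(farms)
        out = predict_at_points(self._points(crop="barley"), farms, ind)
        assert (out["tier"] == "unmatched").all()
        assert out["n_input_med"].isna().all()

    def test_point_region_must_exist(self):
        farms = _toy_farms(5)
        ind = compute_indicators(farms)
        pts = self._points().assign(region="R99")
        with pytest.raises(ValueError, match="R99"):
            predict_at_points(pts, farms, ind)

    def test_raising_cutoff_never_adds_tier_one_matches(
            self, small_sim, small_indicators, small_config):
        counts = []
        for cutoff in (5, 15, 40):
            out = predict_at_points(small_sim.points, small_sim.farms,
                                    small_indicators, min_group_size=cutoff,
                                    crops=small_config.crops)
            counts.append(int((out["tier"] == "1").sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_tier_one_beats_region_mean_prediction(
            self, small_sim, small_indicators, small_predicted):
        # the crop x altitude grouping must capture more point-level truth
        # than a flat regional mean
        gt = small_sim.ground_truth.points.set_index("point_id")
        pred = small_predicted.set_index("point_id")
        mask = (pred["tier"] == "1") & gt["true_manure_share_n"].notna()
        region_mean = small_indicators.groupby("region")["manure_share_n"].mean()
        pts = small_sim.points.set_index("point_id")
        flat = pts.loc[mask, "region"].map(region_mean)
        truth = gt.loc[mask, "true_manure_share_n"]
        r_tier = np.corrcoef(pred.loc[mask, "manure_share_n_med"], truth)[0, 1]
        r_flat = np.corrcoef(flat, truth)[0, 1]
        assert r_tier > r_flat


class TestKruskalWallis:
    def test_identical_values_not_significant(self):
        df = pd.DataFrame({"region": "A", "group": ["g1"] * 3 + ["g2"] * 3,
                           "value": 5.0})
        res, pct = within_region_kw_test(df, "value")
        assert res.loc[0, "p"] == 1.0
        assert pct == 0.0

    def test_strongly_shifted_groups_significant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "region": "A",
            "group": ["g1"] * 20 + ["g2"] * 20,
            "value": np.r_[rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)],
        })
        res, pct = within_region_kw_test(df, "value")
        assert res.loc[0, "p"] < 0.05
        assert pct == 100.0

    def test_statistic_matches_hand_computed_ranks(self):
        # groups {1,2,3} vs {10,11,12}: ranks 1-3 and 4-6,
        # H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 27/7
        df = pd.DataFrame({"region": "A", "group": ["a"] * 3 + ["b"] * 3,
                           "value": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        res, _ = within_region_kw_test(df, "value")
        assert res.loc[0, "chi2"] == pytest.approx(27.0 / 7.0)
        stat, _ = sps.kruskal([1, 2, 3], [10, 11, 12])
        assert res.loc[0, "chi2"] == pytest.approx(stat)

    def test_degenerate_region_excluded(self):
        df = pd.DataFrame({"region": ["A", "A", "B", "B", "B", "B"],
                           "group": ["g1", "g2", "g1", "g1", "g2", "g2"],
                           "value": [1.0, 2.0, 1.0, 2.0, 3.0, 4.0]})
        res, _ = within_region_kw_test(df, "value")
        assert list(res["region"]) == ["B"]
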