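"""Predict farm management at soil-monitoring points.

Farms are never geolocated in survey microdata, so management at a
monitoring point is estimated from the farms that grow the point's crop
nearby, in three tiers of decreasing specificity:

1. same region, altitude class and crop, if at least ``min_group_size``
   farms qualify (the cut-off protects farm anonymity);
2. same region and crop, ignoring altitude;
3. geographically closest farms with the same land-use class within the
   same country, accumulated region by region (ordered by great-circle
   distance between region centroids) until the cut-off is met.

Within a group each farm is weighted by

    w_i = sqrt( (area_i / UAA_i) × (area_i / total_area) )

where ``area_i`` is the farm's area of the point's crop, ``UAA_i`` its
utilised agricultural area and ``total_area`` the summed crop area of
the group: the first factor rewards specialisation in the crop, the
second representativeness of regional production. Group-level summaries
are weighted medians and weighted standard deviations; the probability
of organic farming is the organic share of the group's crop area.

A Kruskal–Wallis rank-sum test per region checks that the crop ×
altitude grouping captures real within-region management differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crops import Crop, DEFAULT_CROPS, land_use_map

DEFAULT_MIN_GROUP_SIZE = 15

#: columns of the per-farm indicator table that are metadata, not indicators
_META_COLS = {"farm_id", "year", "region", "country", "altitude_class",
              "farm_type", "size_class", "uaa_ha", "organic", "livestock_units"}

TIER_1, TIER_2, TIER_3, UNMATCHED = "1", "2", "3", "unmatched"


def indicator_columns(indicators: pd.DataFrame) -> list[str]:
    """The indicator columns of a per-farm indicator table."""
    return [c for c in indicators.columns if c not in _META_COLS]


def farm_weight(area_i, uaa_i, total_area):
    """Eq.-style farm weight sqrt((area/UAA) × (area/total))."""
    a = np.asarray(area_i, dtype=float)
    u = np.asarray(uaa_i, dtype=float)
    t = np.asarray(total_area, dtype=float)
    if np.any(u <= 0) or np.any(t <= 0):
        raise ValueError("UAA and total area must be > 0")
    if np.any(a <= 0):
        raise ValueError("crop area must be > 0 for a group member")
    if np.any(a > u * (1 + 1e-9)) or np.any(a > t * (1 + 1e-9)):
        raise ValueError("crop area cannot exceed UAA or the group total")
    w = np.sqrt((a / u) * (a / t))
    return w.item() if w.ndim == 0 else w


def weighted_median(values, weights) -> float:
    """Lower weighted median.

    The smallest value whose cumulative weight reaches half the total
    weight; with equal weights this is the ordinary lower median.
    Missing values are dropped pairwise; NaN if nothing remains.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    keep = ~np.isnan(v)
    v, w = v[keep], w[keep]
    if v.size == 0:
        return float("nan")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and > 0")
    order = np.argsort(v, kind="mergesort")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1], side="left"))
    return float(v[idx])


def weighted_sd(values, weights) -> float:
    """Frequency-weighted (population) standard deviation."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    keep = ~np.isnan(v)
    v, w = v[keep], w[keep]
    if v.size == 0:
        return float("nan")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and > 0")
    mean = np.average(v, weights=w)
    return float(np.sqrt(np.average((v - mean) ** 2, weights=w)))


@dataclass
class ManagementGroup:
    """The set of farms backing one prediction, with matching provenance."""

    tier: str
    key: tuple
    farm_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    weights: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    @property
    def n_farms(self) -> int:
        return len(self.farm_ids)


def _farm_crop_long(farms: pd.DataFrame, indicators: pd.DataFrame,
                    crops: tuple[Crop, ...] = DEFAULT_CROPS) -> pd.DataFrame:
    """One row per (farm, crop with positive area), carrying indicators."""
    area_cols = [c for c in farms.columns if c.startswith("area_")]
    long = farms.melt(
        id_vars=["farm_id", "region", "country", "altitude_class", "uaa_ha", "organic"],
        value_vars=area_cols, var_name="crop", value_name="area")
    long["crop"] = long["crop"].str.removeprefix("area_")
    long = long[long["area"] > 0].copy()
    lu = land_use_map(crops)
    long["land_use"] = long["crop"].map(lu)
    if long["land_use"].isna().any():
        bad = sorted(long.loc[long["land_use"].isna(), "crop"].unique())
        raise KeyError(f"crops without land-use mapping: {bad}")
    cols = indicator_columns(indicators)
    long = long.merge(indicators[["farm_id"] + cols], on="farm_id", how="left")
    return long


def _group_summary(sub: pd.DataFrame, cols: list[str]) -> pd.Series:
    area = sub["area"].to_numpy(dtype=float)
    uaa = sub["uaa_ha"].to_numpy(dtype=float)
    total = area.sum()
    w = np.sqrt((area / uaa) * (area / total))
    organic = sub["organic"].to_numpy(dtype=bool)
    rec: dict[str, float] = {
        "n_farms": float(len(sub)),
        "organic_probability": float(area[organic].sum() / total),
    }
    for c in cols:
        v = sub[c].to_numpy(dtype=float)
        rec[f"{c}_med"] = weighted_median(v, w)
        rec[f"{c}_sd"] = weighted_sd(v, w)
    return pd.Series(rec)


def _group_stats(long: pd.DataFrame, keys: list[str], min_group_size: int,
                 cols: list[str]) -> pd.DataFrame:
    sizes = long.groupby(keys, observed=True)["farm_id"].size()
    big = sizes[sizes >= min_group_size].index
    if len(big) == 0:
        return pd.DataFrame()
    sel = long.set_index(keys).loc[big].reset_index()
    out = sel.groupby(keys, observed=True).apply(
        _group_summary, cols, include_groups=False)
    return out.reset_index()


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between WGS84 lon/lat pairs, km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 6371.0 * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _landuse_farm_table(long: pd.DataFrame, land_use: str) -> pd.DataFrame:
    """Per-farm aggregate over all crops of one land-use class."""
    sub = long[long["land_use"] == land_use]
    if sub.empty:
        return sub
    agg = sub.groupby("farm_id", as_index=False).agg(
        area=("area", "sum"), uaa_ha=("uaa_ha", "first"),
        organic=("organic", "first"), region=("region", "first"),
        country=("country", "first"),
        **{c: (c, "first") for c in sub.columns
           if c not in {"farm_id", "area", "uaa_ha", "organic", "region",
                        "country", "crop", "land_use", "altitude_class"}})
    return agg


def _tier3_members(long: pd.DataFrame, region_centroids: pd.DataFrame,
                   region: str, country: str, land_use: str,
                   min_group_size: int) -> pd.DataFrame | None:
    """Accumulate whole regions of the same country by centroid distance."""
    cent = region_centroids.set_index("region")
    if region not in cent.index:
        return None
    same = cent[cent["country"] == country]
    d = haversine_km(same["lon"].to_numpy(), same["lat"].to_numpy(),
                     float(cent.loc[region, "lon"]), float(cent.loc[region, "lat"]))
    ordered = same.index.to_numpy()[np.argsort(d, kind="mergesort")]
    table = _landuse_farm_table(long, land_use)
    if table.empty:
        return None
    picked: list[pd.DataFrame] = []
    n = 0
    for reg in ordered:
        chunk = table[table["region"] == reg]
        if chunk.empty:
            continue
        picked.append(chunk)
        n += len(chunk)
        if n >= min_group_size:
            return pd.concat(picked, ignore_index=True)
    return None


def match_point(point, farms: pd.DataFrame, indicators: pd.DataFrame,
                min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
                region_centroids: pd.DataFrame | None = None,
                crops: tuple[Crop, ...] = DEFAULT_CROPS) -> ManagementGroup:
    """Match one soil point to its management group, reporting the tier."""
    long = _farm_crop_long(farms, indicators, crops)
    region, alt = point["region"], point["altitude_class"]
    crop = point["land_cover"]
    t1 = long[(long["region"] == region) & (long["altitude_class"] == alt)
              & (long["crop"] == crop)]
    if len(t1) >= min_group_size:
        return _members_group(TIER_1, (region, alt, crop), t1)
    t2 = long[(long["region"] == region) & (long["crop"] == crop)]
    if len(t2) >= min_group_size:
        return _members_group(TIER_2, (region, crop), t2)
    if region_centroids is not None:
        lu = land_use_map(crops).get(crop)
        members = _tier3_members(long, region_centroids, region,
                                 point["country"], lu, min_group_size)
        if members is not None:
            return _members_group(TIER_3, (point["country"], lu), members)
    return ManagementGroup(UNMATCHED, (region, alt, crop))


def _members_group(tier: str, key: tuple, sub: pd.DataFrame) -> ManagementGroup:
    area = sub["area"].to_numpy(dtype=float)
    uaa = sub["uaa_ha"].to_numpy(dtype=float)
    w = np.sqrt((area / uaa) * (area / area.sum()))
    return ManagementGroup(tier, key, sub["farm_id"].to_numpy(), w)


def predict_at_points(points: pd.DataFrame, farms: pd.DataFrame,
                      indicators: pd.DataFrame,
                      min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
                      region_centroids: pd.DataFrame | None = None,
                      crops: tuple[Crop, ...] = DEFAULT_CROPS) -> pd.DataFrame:
    """Predict every management indicator at every soil point.

    Returns one row per point with ``<indicator>_med`` and
    ``<indicator>_sd`` columns, the organic probability, the matching
    tier and the number of farms behind the prediction. Unmatched points
    carry all-missing indicators.
    """
    missing_regions = set(points["region"]) - set(farms["region"])
    if missing_regions:
        raise ValueError(f"points reference regions absent from the farm table: "
                         f"{sorted(missing_regions)}")
    long = _farm_crop_long(farms, indicators, crops)
    cols = indicator_columns(indicators)
    stat_cols = (["n_farms", "organic_probability"]
                 + [f"{c}_{s}" for c in cols for s in ("med", "sd")])

    t1 = _group_stats(long, ["region", "altitude_class", "crop"], min_group_size, cols)
    t2 = _group_stats(long, ["region", "crop"], min_group_size, cols)

    base = points[["point_id", "region", "country", "altitude_class", "land_cover"]].copy()
    base = base.rename(columns={"land_cover": "crop"})

    out = base.merge(t1, on=["region", "altitude_class", "crop"], how="left") \
        if not t1.empty else base.assign(**{c: np.nan for c in stat_cols})
    out["tier"] = np.where(out["n_farms"].notna(), TIER_1, UNMATCHED)

    need = out["n_farms"].isna()
    if need.any() and not t2.empty:
        fallback = base.loc[need, ["region", "crop"]].merge(
            t2, on=["region", "crop"], how="left")
        out.loc[need, stat_cols] = fallback[stat_cols].to_numpy()
        out.loc[need & out["n_farms"].notna(), "tier"] = TIER_2

    need = out["n_farms"].isna()
    if need.any() and region_centroids is not None:
        lu_map = land_use_map(crops)
        needy = out.loc[need, ["region", "country", "crop"]].copy()
        needy["land_use"] = needy["crop"].map(lu_map)
        for (region, country, lu), sub in needy.groupby(
                ["region", "country", "land_use"], observed=True):
            members = _tier3_members(long, region_centroids, region, country,
                                     lu, min_group_size)
            if members is None:
                continue
            summary = _group_summary(members, cols)
            out.loc[sub.index, stat_cols] = summary[stat_cols].to_numpy()
            out.loc[sub.index, "tier"] = TIER_3

    out["tier"] = out["tier"].where(out["n_farms"].notna(), UNMATCHED)
    out["n_farms"] = out["n_farms"].fillna(0).astype(int)
    return out.drop(columns=["crop"])


def within_region_kw_test(table: pd.DataFrame, value_col: str,
                          group_col: str = "group", region_col: str = "region",
                          alpha: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Kruskal–Wallis test of the grouping within each region.

    For every region with at least two groups of at least two
    observations, tests whether ``value_col`` differs between groups.
    Returns the per-region (χ², p) table and the percentage of regions
    significant at ``alpha``. Regions where the test is degenerate
    (identical values throughout) get χ² = 0, p = 1.
    """
    rows = []
    for region, sub in table.groupby(region_col, observed=True):
        groups = [g[value_col].dropna().to_numpy()
                  for _, g in sub.groupby(group_col, observed=True)]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        if len(np.unique(np.concatenate(groups))) == 1:
            stat, p = 0.0, 1.0  # all values identical: no evidence of grouping
        else:
            stat, p = sps.kruskal(*groups)
        rows.append({"region": region, "chi2": float(stat), "p": float(p)})
    res = pd.DataFrame(rows, columns=["region", "chi2", "p"])
    pct = float(100.0 * (res["p"] < alpha).mean()) if len(res) else float("nan")
    return res, pct
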