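"""Seeded synthetic farm surveys, tillage tables and soil points.

Real farm microdata and soil-monitoring tables are access-restricted,
so every downstream stage of this package is exercised on synthetic
data with a *known* management → SOC relationship:

* Farms get a region, an altitude class, a crop-area composition
  (Dirichlet around a dominant crop, restricted mostly to the farm's
  land-use specialisation), log-normal livestock densities and mineral
  fertiliser rates, and a Bernoulli organic flag whose probability
  rises with altitude. Positive, right-skewed distributions match the
  character of farm surveys; their parameters are not estimates of any
  real survey.
* The tillage table covers every region × farm-size × farm-type cell
  with Dirichlet-split areas, conventional tillage dominating.
* Each soil point draws a region, a crop from the regional crop mix,
  an altitude and edaphic covariates. Its *true* management indicator
  values are the weighted group summaries assigned by the same tiered
  matching procedure the prediction stage uses, so a correctly
  implemented prediction stage recovers them exactly. The
  expected SOC stock is the point's pedoclimatic-zone baseline plus a
  configured linear effect of each chosen indicator; Gaussian noise is
  added, bulk density follows a configured linear model of the edaphic
  covariates, and the later-date OC concentration is back-computed so
  that the stock equation reproduces the true stock exactly. The
  earlier-date OC encodes a configurable yearly concentration change
  plus measurement noise.

All draws derive from ``numpy.random.default_rng`` seeded per stage
from the config seed, so identical configs give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crops import ARABLE, Crop, DEFAULT_CROPS, GRASSLAND, TREE, land_use_map
from .indicators import (DEFAULT_EXCRETION, ExcretionTable, altitude_class,
                         compute_indicators)
from .predict import predict_at_points

CLIMATES = ("alpine", "atlantic", "continental", "mediterranean")
TEXTURES = ("loamy", "sandy")

#: default typical 0-20 cm stocks per pedoclimatic zone, Mg C ha^-1
DEFAULT_ZONE_BASELINES = {
    "alpine_loamy": 90.0, "alpine_sandy": 70.0,
    "atlantic_loamy": 75.0, "atlantic_sandy": 55.0,
    "continental_loamy": 60.0, "continental_sandy": 45.0,
    "mediterranean_loamy": 50.0, "mediterranean_sandy": 38.0,
}

#: default true management -> stock slopes (Mg C ha^-1 per indicator unit),
#: signs follow the expected directions: manure share, ley share and
#: organic probability all favour SOC.
DEFAULT_TRUE_EFFECTS = {
    "manure_share_n": 15.0,
    "ley_share": 25.0,
    "organic_probability": 10.0,
}

#: default generative bulk-density model on point covariates
DEFAULT_BD_COEFFICIENTS = {
    "intercept": 1.60, "ph": -0.02, "total_n": -0.05,
    "sand": 0.0, "clay": 0.0, "sand_clay": -5.0e-5,
}

_CLIMATE_MAP_MM = {"alpine": 1100.0, "atlantic": 900.0,
                   "continental": 650.0, "mediterranean": 480.0}
_CLIMATE_ALT_M = {"alpine": 750.0, "atlantic": 150.0,
                  "continental": 300.0, "mediterranean": 420.0}
_INTENSIVE_CROPS = {"potato", "sugar_beet", "vegetables", "maize"}
_ALT_ORGANIC_MULT = {"<300": 1.0, "300-600": 1.4, ">600": 2.5}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study, with validation."""

    seed: int = 0
    n_regions: int = 4
    n_farms_per_region: int = 300
    n_points: int = 1200
    crops: tuple[Crop, ...] = DEFAULT_CROPS
    altitude_breaks_m: tuple[float, float] = (300.0, 600.0)
    regions_per_country: int = 2
    organic_fraction: float = 0.10
    true_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS))
    zone_baselines: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_BASELINES))
    noise_sd_stock: float = 8.0
    bd_model_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_BD_COEFFICIENTS))
    bd_noise_sd: float = 0.05
    measurement_sd_oc: float = 0.5
    delta_mean: float = 0.0
    delta_sd: float = 0.05
    bd_measured_fraction: float = 0.35
    zone_missing_fraction: float = 0.15
    landuse_change_fraction: float = 0.02
    year_t0: int = 2009
    year_t1: int = 2018
    #: group-size cut-off used when assigning the *true* management of a
    #: point from its matched farm group (mirrors the prediction default)
    matching_min_group_size: int = 15
    #: scales the log-normal spread of livestock and fertiliser draws —
    #: the within-group management variance of real surveys is unknown,
    #: so it is an explicit free parameter.
    within_group_spread: float = 1.0
    excretion: ExcretionTable = DEFAULT_EXCRETION

    def __post_init__(self) -> None:
        for fld in ("noise_sd_stock", "bd_noise_sd", "measurement_sd_oc",
                    "delta_sd", "within_group_spread"):
            if getattr(self, fld) < 0:
                raise ValueError(f"config field {fld} must be >= 0")
        for fld in ("n_regions", "n_farms_per_region", "n_points"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"config field {fld} must be positive")
        lo, hi = self.altitude_breaks_m
        if not lo < hi:
            raise ValueError("config field altitude_breaks_m must be strictly increasing")
        if not self.crops:
            raise ValueError("config field crops must be non-empty")
        for frac in ("organic_fraction", "bd_measured_fraction",
                     "zone_missing_fraction", "landuse_change_fraction"):
            if not 0 <= getattr(self, frac) <= 1:
                raise ValueError(f"config field {frac} must be in [0, 1]")
        for zone, base in self.zone_baselines.items():
            if base <= 0:
                raise ValueError(f"config field zone_baselines[{zone!r}] must be positive")
        if self.year_t1 <= self.year_t0:
            raise ValueError("config field year_t1 must be after year_t0")


def noiseless(config: SynthConfig, bd_exact: bool = True) -> SynthConfig:
    """A copy of the config with every noise source switched off."""
    return replace(config, noise_sd_stock=0.0, measurement_sd_oc=0.0,
                   delta_sd=0.0, bd_noise_sd=0.0 if bd_exact else config.bd_noise_sd,
                   zone_missing_fraction=0.0, landuse_change_fraction=0.0,
                   bd_measured_fraction=1.0)


def region_table(config: SynthConfig) -> pd.DataFrame:
    """Regions with country membership, climate and a synthetic centroid."""
    i = np.arange(config.n_regions)
    return pd.DataFrame({
        "region": [f"R{k + 1:02d}" for k in i],
        "country": [f"C{k // config.regions_per_country + 1:02d}" for k in i],
        "climate": [CLIMATES[k % len(CLIMATES)] for k in i],
        "lon": -8.0 + 2.5 * (i % 10),
        "lat": 38.0 + 2.0 * (i // 10) + 0.7 * (i % 5),
    })


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _size_class(uaa: np.ndarray) -> np.ndarray:
    return np.where(uaa < 20, "<20", np.where(uaa <= 100, "20-100", ">100"))


def generate_farms(config: SynthConfig) -> pd.DataFrame:
    """Synthetic farm-survey table, one row per farm-year."""
    rng = _rng(config, 1)
    regions = region_table(config)
    lu_map = land_use_map(config.crops)
    codes = [c.code for c in config.crops]
    by_lu = {lu: [c.code for c in config.crops if c.land_use == lu]
             for lu in (ARABLE, GRASSLAND, TREE)}
    present_lu = [lu for lu in (ARABLE, GRASSLAND, TREE) if by_lu[lu]]

    n = config.n_regions * config.n_farms_per_region
    region_idx = np.repeat(np.arange(config.n_regions), config.n_farms_per_region)

    # region-level character: crop-mix preferences and input-level factors
    mix_pref = {lu: rng.dirichlet(np.full(len(by_lu[lu]), 1.2), size=config.n_regions)
                for lu in present_lu if len(by_lu[lu]) > 0}
    # arable dominates European agricultural land cover, then grassland
    lu_alpha = {ARABLE: 6.0, GRASSLAND: 3.0, TREE: 1.5}
    lu_share = rng.dirichlet([lu_alpha[lu] for lu in present_lu],
                             size=config.n_regions)
    livestock_factor = np.exp(rng.normal(0.0, 0.4, config.n_regions))
    fert_factor = np.exp(rng.normal(0.0, 0.3, config.n_regions))

    climate = regions["climate"].to_numpy()[region_idx]
    alt_base = np.array([_CLIMATE_ALT_M[c] for c in climate])
    altitude_m = np.maximum(0.0, alt_base * np.exp(rng.normal(0.0, 0.55, n)))
    alt_cls = altitude_class(altitude_m, config.altitude_breaks_m)

    # land-use specialisation and dominant crop per farm
    spec_idx = np.array([rng.choice(len(present_lu), p=lu_share[r])
                         for r in region_idx])
    farm_lu = np.array(present_lu, dtype=object)[spec_idx]
    dominant = np.empty(n, dtype=object)
    for k, lu in enumerate(present_lu):
        mask = spec_idx == k
        if not mask.any():
            continue
        pool = by_lu[lu]
        for r in np.unique(region_idx[mask]):
            m = mask & (region_idx == r)
            dominant[m] = rng.choice(pool, size=m.sum(), p=mix_pref[lu][r])

    # Dirichlet crop areas around the dominant crop
    alpha = np.full((n, len(codes)), 0.05)
    for j, code in enumerate(codes):
        same_lu = np.array([lu_map[code] == lu for lu in farm_lu])
        alpha[:, j] = np.where(same_lu, 0.4, 0.05)
        alpha[:, j] = np.where(dominant == code, 8.0, alpha[:, j])
    gam = rng.gamma(alpha)
    shares = gam / gam.sum(axis=1, keepdims=True)
    shares = np.where(shares < 0.03, 0.0, shares)          # sparsify tiny slivers
    shares = shares / shares.sum(axis=1, keepdims=True)

    uaa = np.exp(rng.normal(np.log(30.0), 0.9, n))
    areas = shares * uaa[:, None]

    grass_like = np.zeros(n)
    for j, code in enumerate(codes):
        if lu_map[code] == GRASSLAND or code in ("temp_grass", "lucerne"):
            grass_like += shares[:, j]
    sigma = 0.6 * config.within_group_spread
    lu_density = (0.08 + 0.9 * grass_like) * livestock_factor[region_idx] \
        * np.exp(rng.normal(0.0, sigma, n))
    no_stock = (grass_like < 0.05) & (rng.random(n) < 0.5)
    livestock = np.where(no_stock, 0.0, lu_density * uaa)

    organic_p = np.clip(
        config.organic_fraction
        * np.vectorize(_ALT_ORGANIC_MULT.get)(alt_cls).astype(float), 0.0, 1.0)
    organic = rng.random(n) < organic_p

    intensive = np.isin(dominant, list(_INTENSIVE_CROPS))
    crop_factor = np.where(intensive, 1.5, np.where(dominant == "temp_grass", 0.5, 1.0))
    fsig = 0.5 * config.within_group_spread
    base_rates = {"n": 70.0, "p": 15.0, "k": 40.0}
    mineral = {}
    for nut, base in base_rates.items():
        rate = base * crop_factor * fert_factor[region_idx] \
            * np.exp(rng.normal(0.0, fsig, n))
        rate = np.where(organic, rate * 0.15, rate)
        mineral[nut] = rate * uaa

    farms = pd.DataFrame({
        "farm_id": [f"F{k + 1:06d}" for k in range(n)],
        "year": rng.choice([2018, 2019, 2020], n),
        "region": regions["region"].to_numpy()[region_idx],
        "country": regions["country"].to_numpy()[region_idx],
        "altitude_m": altitude_m,
        "altitude_class": alt_cls,
        "farm_type": farm_lu,
        "uaa_ha": uaa,
        "organic": organic,
        "livestock_units": livestock,
        "mineral_n_kg": mineral["n"],
        "mineral_p_kg": mineral["p"],
        "mineral_k_kg": mineral["k"],
    })
    farms["size_class"] = _size_class(uaa)
    for j, code in enumerate(codes):
        farms[f"area_{code}"] = areas[:, j]
    return farms


def generate_tillage_table(config: SynthConfig) -> pd.DataFrame:
    """Aggregate tillage areas per region × farm-size × farm-type cell."""
    rng = _rng(config, 2)
    regions = region_table(config)["region"]
    sizes = ["<20", "20-100", ">100"]
    types = [ARABLE, GRASSLAND, TREE]
    rows = []
    for region in regions:
        adoption = rng.uniform(0.0, 1.0)  # regional conservation-tillage uptake
        for size in sizes:
            for ftype in types:
                total = np.exp(rng.normal(np.log(5e3), 0.8))
                shares = rng.dirichlet([6.0, 1.0 + 4.0 * adoption,
                                        0.5 + 2.0 * adoption])
                rows.append({
                    "region": region, "size_class": size, "farm_type": ftype,
                    "conventional_ha": total * shares[0],
                    "conservation_ha": total * shares[1],
                    "zero_ha": total * shares[2],
                })
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """True per-point management, expected stocks and generative coefficients."""

    points: pd.DataFrame
    true_effects: dict
    zone_baselines: dict
    bd_coefficients: dict


def generate_soil_points(config: SynthConfig, farms: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthetic monitoring points plus their generative ground truth."""
    regions = region_table(config)
    unknown = set(farms["region"]) - set(regions["region"])
    if unknown:
        raise ValueError(f"farm table references regions outside the config: "
                         f"{sorted(unknown)}")
    rng = _rng(config, 3)
    tillage = generate_tillage_table(config)
    lu_map = land_use_map(config.crops)
    n = config.n_points

    ridx = rng.integers(0, config.n_regions, n)
    region = regions["region"].to_numpy()[ridx]
    country = regions["country"].to_numpy()[ridx]
    climate = regions["climate"].to_numpy()[ridx]
    lon = regions["lon"].to_numpy()[ridx] + rng.normal(0.0, 0.4, n)
    lat = regions["lat"].to_numpy()[ridx] + rng.normal(0.0, 0.4, n)

    alt_base = np.array([_CLIMATE_ALT_M[c] for c in climate])
    altitude_m = np.maximum(0.0, alt_base * np.exp(rng.normal(0.0, 0.55, n)))
    alt_cls = altitude_class(altitude_m, config.altitude_breaks_m)

    # crop drawn from the regional crop-area mix of the farm survey
    area_cols = [c for c in farms.columns if c.startswith("area_")]
    reg_mix = farms.groupby("region")[area_cols].sum()
    crop = np.empty(n, dtype=object)
    for reg in np.unique(region):
        mask = region == reg
        w = reg_mix.loc[reg].to_numpy(dtype=float)
        w = w / w.sum()
        crop[mask] = rng.choice([c.removeprefix("area_") for c in area_cols],
                                size=mask.sum(), p=w)
    land_use = np.array([lu_map[c] for c in crop], dtype=object)

    sand = rng.uniform(15.0, 85.0, n)
    clay = rng.uniform(5.0, np.minimum(45.0, 95.0 - sand))
    ph = rng.uniform(4.5, 8.2, n)
    total_n = np.exp(rng.normal(np.log(1.8), 0.4, n))
    map_mm = np.array([_CLIMATE_MAP_MM[c] for c in climate]) + rng.normal(0, 80.0, n)
    coarse_frag = rng.beta(2.0, 8.0, n) * 0.6
    texture = np.where(sand >= 50.0, "sandy", "loamy")
    zone = np.array([f"{c}_{t}" for c, t in zip(climate, texture)], dtype=object)
    missing_zone = [z for z in np.unique(zone) if z not in config.zone_baselines]
    if missing_zone:
        raise ValueError(f"zone_baselines lacks entries for {missing_zone}")

    # True indicators are the group summaries the tiered matching procedure
    # itself assigns at the default cut-off: the management experienced at a
    # point is the management of the farms that represent it, so downstream
    # parameter recovery isolates the modelling stages from irreducible
    # matching error. Unmatched points contribute no management effect.
    keys = pd.DataFrame({
        "point_id": [f"P{k + 1:06d}" for k in range(n)],
        "region": region, "country": country,
        "altitude_class": alt_cls, "land_cover": crop,
    })
    ind = compute_indicators(farms, config.crops, config.excretion, tillage)
    matched = predict_at_points(keys, farms, ind,
                                min_group_size=config.matching_min_group_size,
                                region_centroids=region_table(config),
                                crops=config.crops).set_index("point_id")
    matched = matched.loc[keys["point_id"]]
    truth = pd.DataFrame({"point_id": keys["point_id"]})
    contrib = np.zeros(n)
    for key, slope in config.true_effects.items():
        col = key if key == "organic_probability" else f"{key}_med"
        vals = matched[col].to_numpy(dtype=float)
        truth[f"true_{key}"] = vals
        contrib += slope * np.nan_to_num(vals)
    baseline = np.array([config.zone_baselines[z] for z in zone])
    expected_stock = baseline + contrib
    stock_true = np.maximum(1.0, expected_stock + rng.normal(0, config.noise_sd_stock, n))

    c = config.bd_model_coefficients
    bd_true = (c.get("intercept", 0.0) + c.get("ph", 0.0) * ph
               + c.get("total_n", 0.0) * total_n + c.get("sand", 0.0) * sand
               + c.get("clay", 0.0) * clay + c.get("sand_clay", 0.0) * sand * clay
               + rng.normal(0.0, config.bd_noise_sd, n))
    oc_t1 = stock_true / (bd_true * 20.0 * 0.1 * (1.0 - coarse_frag))
    delta_true = rng.normal(config.delta_mean, config.delta_sd, n)
    years = config.year_t1 - config.year_t0
    oc_t0 = np.maximum(0.01, oc_t1 - years * delta_true
                       + rng.normal(0.0, config.measurement_sd_oc, n))

    bd_measured = np.where(rng.random(n) < config.bd_measured_fraction, bd_true, np.nan)
    zone_col = np.where(rng.random(n) < config.zone_missing_fraction, None, zone)
    changed = rng.random(n) < config.landuse_change_fraction
    other_lu = {ARABLE: GRASSLAND, GRASSLAND: ARABLE, TREE: ARABLE}
    land_use_t0 = np.where(changed,
                           [other_lu[lu] for lu in land_use], land_use)

    points = pd.DataFrame({
        "point_id": truth["point_id"],
        "lon": lon, "lat": lat,
        "region": region, "country": country,
        "altitude_m": altitude_m, "altitude_class": alt_cls,
        "land_cover": crop, "land_use": land_use, "land_use_t0": land_use_t0,
        "oc_t0": oc_t0, "oc_t1": oc_t1,
        "year_t0": config.year_t0, "year_t1": config.year_t1,
        "bd_measured": bd_measured, "coarse_frag": coarse_frag,
        "sand": sand, "clay": clay, "ph": ph, "total_n": total_n,
        "map_mm": map_mm, "zone": zone_col,
    })
    truth["zone"] = zone
    truth["expected_stock"] = expected_stock
    truth["stock_true"] = stock_true
    truth["bd_true"] = bd_true
    truth["delta_true"] = delta_true
    gt = GroundTruth(points=truth, true_effects=dict(config.true_effects),
                     zone_baselines=dict(config.zone_baselines),
                     bd_coefficients=dict(config.bd_model_coefficients))
    return points, gt


def generate_benchmarks(config: SynthConfig, ground_truth: GroundTruth,
                        points: pd.DataFrame) -> pd.DataFrame:
    """Benchmark table: typical stock and mapped area per zone × land use.

    Typical stocks are the mean *expected* (pre-noise) stocks of the
    stratum's points, so benchmark ratios centre near one by design.
    """
    rng = _rng(config, 4)
    merged = ground_truth.points[["point_id", "zone", "expected_stock"]].merge(
        points[["point_id", "land_use"]], on="point_id")
    rows = []
    for (zone, lu), sub in merged.groupby(["zone", "land_use"], observed=True):
        rows.append({
            "zone": zone, "land_use": lu,
            "typical_stock": float(sub["expected_stock"].mean()),
            "area_ha": float(np.exp(rng.normal(np.log(2e6), 0.5))),
        })
    return pd.DataFrame(rows)


@dataclass
class Simulation:
    """All synthetic tables of one run."""

    config: SynthConfig
    farms: pd.DataFrame
    tillage: pd.DataFrame
    points: pd.DataFrame
    ground_truth: GroundTruth
    benchmarks: pd.DataFrame
    regions: pd.DataFrame


def simulate(config: SynthConfig) -> Simulation:
    """Generate every synthetic table for one seeded configuration."""
    farms = generate_farms(config)
    tillage = generate_tillage_table(config)
    points, gt = generate_soil_points(config, farms)
    benchmarks = generate_benchmarks(config, gt, points)
    return Simulation(config=config, farms=farms, tillage=tillage, points=points,
                      ground_truth=gt, benchmarks=benchmarks,
                      regions=region_table(config))


def write_simulation(sim: Simulation, out_dir, geojson: bool = False) -> dict:
    """Write farms/tillage/points/benchmarks/ground-truth CSVs; return paths."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("farms", sim.farms), ("tillage", sim.tillage),
                     ("points", sim.points), ("benchmarks", sim.benchmarks),
                     ("ground_truth", sim.ground_truth.points),
                     ("regions", sim.regions)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    if geojson:
        feats = [{
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(float(r.lon), 6), round(float(r.lat), 6)]},
            "properties": {"point_id": r.point_id},
        } for r in sim.points.itertuples()]
        p = out / "points.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        paths["points_geojson"] = str(p)
    return paths
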