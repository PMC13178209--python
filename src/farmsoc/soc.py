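"""Soil-organic-carbon metrics for topsoil monitoring points.

Three metrics are computed per point for the 0–20 cm layer:

* **SOC stock** (Mg C ha⁻¹): ``B_d,ref × OC × 20 cm × 0.1 × (1 − C_f)``
  where ``B_d,ref`` is a reference fine-earth bulk density (g cm⁻³)
  predicted from edaphic covariates, ``OC`` the organic-carbon
  concentration (g C kg⁻¹) and ``C_f`` the volumetric coarse-fragment
  fraction. Using a *predicted* reference density for every point —
  including points with a measured density — keeps stock comparisons
  between land uses mass-standardised, because measured density itself
  responds to management.
* **Benchmarked stock**: the observed stock divided by the typical
  stock of the point's pedoclimatic zone and land use (1.0 = at
  benchmark).
* **ΔSOC** (g kg⁻¹ yr⁻¹): the change in OC concentration between two
  survey dates divided by the number of years.

The bulk-density pedotransfer is a land-use-specific ordinary
least-squares regression chosen by exhaustive AIC search over
hierarchy-respecting subsets of {sand, clay, sand×clay, total N, pH,
mean annual precipitation}. OC is never admitted as a predictor: the
predicted density multiplies OC in the stock equation, so admitting OC
would let it enter the stock twice and bias land-use comparisons.

Missing pedoclimatic zones are imputed with a random-forest classifier
on soil and site covariates. Cleaning removes organic soils
(OC > 160 g C kg⁻¹), points whose land-cover class changed between
surveys (change metric only), and implausibly large concentration
changes (> 100% relative over the period or > 3 g kg⁻¹ yr⁻¹ absolute).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

BD_CLIP = (0.1, 2.2)  # plausible fine-earth bulk densities, g cm^-3
ORGANIC_OC_LIMIT = 160.0    # g C kg^-1, strictly above -> organic soil, removed
DELTA_ABS_LIMIT = 3.0       # g kg^-1 yr^-1, strictly above -> removed
DELTA_REL_LIMIT = 1.0       # |whole-period change| / oc_t0, strictly above -> removed

#: candidate pedotransfer terms; ``a:b`` denotes the product of a and b
BD_CANDIDATE_TERMS = ("sand", "clay", "sand:clay", "total_n", "ph", "map_mm")
_FORBIDDEN_BD_VARS = {"oc", "oc_t0", "oc_t1"}


def soc_stock(bd_ref, oc, coarse_frag):
    """0–20 cm SOC stock in Mg C ha⁻¹.

    ``bd_ref`` g cm⁻³, ``oc`` g C kg⁻¹, ``coarse_frag`` volume fraction.
    """
    bd = np.asarray(bd_ref, dtype=float)
    c = np.asarray(oc, dtype=float)
    cf = np.asarray(coarse_frag, dtype=float)
    out = bd * c * 20.0 * 0.1 * (1.0 - cf)
    return out.item() if out.ndim == 0 else out


def benchmark_ratio(stock, typical_stock):
    """Observed stock divided by the pedoclimatic typical stock."""
    t = np.asarray(typical_stock, dtype=float)
    if np.any(t[~np.isnan(t)] <= 0):
        raise ValueError("typical stock must be > 0")
    out = np.asarray(stock, dtype=float) / t
    return out.item() if out.ndim == 0 else out


def delta_soc(oc_t0, oc_t1, year_t0, year_t1):
    """Yearly change in OC concentration, g kg⁻¹ yr⁻¹."""
    y0 = np.asarray(year_t0, dtype=float)
    y1 = np.asarray(year_t1, dtype=float)
    if np.any(y1 <= y0):
        raise ValueError("year_t1 must be after year_t0")
    out = (np.asarray(oc_t1, dtype=float) - np.asarray(oc_t0, dtype=float)) / (y1 - y0)
    return out.item() if out.ndim == 0 else out


def _term_vars(term: str) -> list[str]:
    return term.split(":")


def design_matrix(df: pd.DataFrame, terms: tuple[str, ...] | list[str]) -> pd.DataFrame:
    """Intercept + the named terms; ``a:b`` is the elementwise product."""
    out = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for term in terms:
        cols = _term_vars(term)
        v = df[cols[0]].to_numpy(dtype=float).copy()
        for c in cols[1:]:
            v = v * df[c].to_numpy(dtype=float)
        out[term] = v
    return out


def enumerate_bd_candidates(
        terms: tuple[str, ...] = BD_CANDIDATE_TERMS) -> list[tuple[str, ...]]:
    """All hierarchy-respecting predictor subsets.

    An interaction term appears only together with both of its main
    effects. For the default six terms this yields 40 candidate models
    (including the intercept-only model).
    """
    mains = [t for t in terms if ":" not in t]
    inters = [t for t in terms if ":" in t]
    out = []
    for r in range(len(mains) + 1):
        for sub in itertools.combinations(mains, r):
            base = tuple(sub)
            out.append(base)
            for ri in range(1, len(inters) + 1):
                for isub in itertools.combinations(inters, ri):
                    if all(set(_term_vars(i)) <= set(sub) for i in isub):
                        out.append(base + isub)
    return out


@dataclass
class BdModel:
    """A fitted land-use-specific bulk-density pedotransfer model."""

    land_use: str
    terms: tuple[str, ...]
    params: pd.Series
    aic: float
    n: int
    sigma: float

    def predict(self, df: pd.DataFrame, clip: tuple[float, float] = BD_CLIP) -> pd.Series:
        """Predict B_d,ref, clipped to a physically plausible range.

        Rows with missing covariates get NaN.
        """
        needed = sorted({v for t in self.terms for v in _term_vars(t)})
        ok = df[needed].notna().all(axis=1) if needed else pd.Series(True, index=df.index)
        pred = pd.Series(np.nan, index=df.index, dtype=float)
        if ok.any():
            x = design_matrix(df.loc[ok].fillna(0.0), self.terms)
            pred.loc[ok] = x.to_numpy() @ self.params.to_numpy()
        return pred.clip(*clip)


def fit_bd_models(points: pd.DataFrame,
                  candidate_terms: tuple[str, ...] = BD_CANDIDATE_TERMS,
                  min_points: int = 30,
                  bd_col: str = "bd_measured") -> dict[str, BdModel]:
    """Select the minimum-AIC bulk-density model per land use.

    OLS fits over every hierarchy-respecting subset of the candidate
    terms; organic-carbon variables are rejected as candidates.
    """
    bad = [t for t in candidate_terms
           if set(_term_vars(t)) & _FORBIDDEN_BD_VARS]
    if bad:
        raise ValueError(f"organic carbon may not predict bulk density: {bad}")
    all_vars = sorted({v for t in candidate_terms for v in _term_vars(t)})
    models: dict[str, BdModel] = {}
    for land_use, sub in points.groupby("land_use", observed=True):
        data = sub.dropna(subset=[bd_col] + all_vars)
        if len(data) < min_points:
            raise ValueError(
                f"land use {land_use!r}: only {len(data)} points with measured "
                f"bulk density and complete covariates (need {min_points})")
        y = data[bd_col].to_numpy(dtype=float)
        n = len(y)
        best = None
        for terms in enumerate_bd_candidates(candidate_terms):
            x = design_matrix(data, terms)
            res = sm.OLS(y, x).fit()
            # Gaussian AIC with the residual variance floored at machine
            # precision so exact-fit candidates stay finite and comparable;
            # candidates are enumerated smallest-first, so on (near-)ties
            # the more parsimonious model is kept.
            sigma2 = max(res.ssr / n, 1e-24)
            aic = n * np.log(sigma2) + 2 * (len(terms) + 1)
            if best is None or aic < best[0] - 1e-9:
                best = (aic, terms, res)
        aic, terms, res = best
        colnames = design_matrix(data.head(1), terms).columns
        models[land_use] = BdModel(
            land_use=land_use, terms=terms,
            params=pd.Series(np.asarray(res.params), index=colnames),
            aic=float(aic), n=len(data), sigma=float(np.sqrt(res.scale)))
    return models


def predict_bd_ref(points: pd.DataFrame, models: dict[str, BdModel],
                   clip: tuple[float, float] = BD_CLIP) -> pd.Series:
    """Reference bulk density for every point from its land-use model."""
    out = pd.Series(np.nan, index=points.index, dtype=float)
    for land_use, model in models.items():
        mask = points["land_use"] == land_use
        if mask.any():
            out.loc[mask] = model.predict(points.loc[mask], clip=clip)
    return out


DEFAULT_ZONE_FEATURES = ("oc_t1", "region", "land_cover", "sand", "clay",
                         "ph", "map_mm", "altitude_m")


def impute_zone(points: pd.DataFrame,
                features: tuple[str, ...] = DEFAULT_ZONE_FEATURES,
                n_trees: int = 500, min_node_size: int = 1, mtry: int = 3,
                seed: int = 0,
                min_class_size: int = 10) -> tuple[pd.Series, float]:
    """Fill missing pedoclimatic zones with a random-forest classifier.

    Trains on points with a known zone (ensemble of ``n_trees`` trees,
    ``mtry`` features per split, minimum node size ``min_node_size``)
    and returns the completed zone series together with the out-of-bag
    error rate of the training fit. Categorical features are integer-
    encoded jointly over training and prediction rows, so prediction
    rows cannot carry unseen levels.
    """
    feats = [f for f in features if f in points.columns]
    enc = pd.DataFrame(index=points.index)
    for f in feats:
        col = points[f]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            enc[f] = pd.factorize(col)[0]
        else:
            enc[f] = col.astype(float).fillna(col.astype(float).median())
    known = points["zone"].notna()
    if not known.any():
        raise ValueError("no training points with a known zone")
    counts = points.loc[known, "zone"].value_counts()
    if (counts < min_class_size).any():
        small = counts[counts < min_class_size]
        raise ValueError(f"zone classes with fewer than {min_class_size} "
                         f"training points: {dict(small)}")
    rf = RandomForestClassifier(
        n_estimators=n_trees, min_samples_leaf=min_node_size,
        max_features=min(mtry, len(feats)), oob_score=len(counts) > 1,
        random_state=seed, n_jobs=1)
    rf.fit(enc.loc[known], points.loc[known, "zone"])
    oob_error = float(1.0 - rf.oob_score_) if len(counts) > 1 else 0.0
    zones = points["zone"].copy()
    if (~known).any():
        zones.loc[~known] = rf.predict(enc.loc[~known])
    return zones, oob_error


@dataclass
class CleanResult:
    """Cleaned analysis sets and the per-filter removal accounting."""

    flags: pd.DataFrame
    stock_set: pd.DataFrame
    delta_set: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)


def clean_records(metrics: pd.DataFrame) -> CleanResult:
    """Apply the cleaning filters and split per-metric analysis sets.

    * ``stock_set`` (stocks and benchmark ratios): drops organic soils
      with OC strictly above 160 g C kg⁻¹ at the stock survey date.
    * ``delta_set`` (ΔSOC): additionally requires OC ≤ 160 at both
      dates, an unchanged land-cover class, a whole-period relative
      change of at most 100% and an absolute change of at most
      3 g kg⁻¹ yr⁻¹ (all strict inequalities).
    """
    f = pd.DataFrame(index=metrics.index)
    oc0 = metrics["oc_t0"].to_numpy(dtype=float)
    oc1 = metrics["oc_t1"].to_numpy(dtype=float)
    f["removed_organic"] = oc1 > ORGANIC_OC_LIMIT
    f["removed_organic_t0"] = oc0 > ORGANIC_OC_LIMIT
    f["removed_landuse_change"] = (
        metrics["land_use_t0"].notna()
        & (metrics["land_use_t0"] != metrics["land_use"]))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(oc1 - oc0) / oc0
    rel_bad = np.where(oc0 > 0, rel > DELTA_REL_LIMIT, oc1 != oc0)
    abs_bad = np.abs(metrics["delta_soc"].to_numpy(dtype=float)) > DELTA_ABS_LIMIT
    f["removed_delta_outlier"] = rel_bad | abs_bad

    stock_set = metrics[~f["removed_organic"]].copy()
    delta_keep = ~(f["removed_organic"] | f["removed_organic_t0"]
                   | f["removed_landuse_change"] | f["removed_delta_outlier"])
    delta_set = metrics[delta_keep].copy()
    counts = {
        "n_input": int(len(metrics)),
        "n_stock": int(len(stock_set)),
        "n_delta": int(len(delta_set)),
        "removed_organic": int(f["removed_organic"].sum()),
        "removed_organic_t0": int(f["removed_organic_t0"].sum()),
        "removed_landuse_change": int(f["removed_landuse_change"].sum()),
        "removed_delta_outlier": int(f["removed_delta_outlier"].sum()),
    }
    return CleanResult(flags=f, stock_set=stock_set, delta_set=delta_set, counts=counts)


def compute_soc_metrics(points: pd.DataFrame, benchmarks: pd.DataFrame,
                        min_bd_points: int = 30,
                        zone_seed: int = 0,
                        ) -> tuple[pd.DataFrame, dict[str, BdModel], CleanResult]:
    """Full metric stage: pedotransfer, stocks, zones, benchmarks, ΔSOC.

    Returns the per-point metric table (with cleaning flags attached),
    the selected bulk-density models and the cleaning report.
    """
    pts = points.copy()
    models = fit_bd_models(pts, min_points=min_bd_points)
    pts["bd_ref"] = predict_bd_ref(pts, models)
    pts["stock"] = soc_stock(pts["bd_ref"], pts["oc_t1"], pts["coarse_frag"])
    if pts["zone"].isna().any():
        pts["zone"], oob = impute_zone(pts, seed=zone_seed)
        pts.attrs["zone_oob_error"] = oob
    bench = benchmarks[["zone", "land_use", "typical_stock"]]
    pts = pts.merge(bench, on=["zone", "land_use"], how="left")
    pts["benchmark_ratio"] = benchmark_ratio(pts["stock"], pts["typical_stock"])
    pts["delta_soc"] = delta_soc(pts["oc_t0"], pts["oc_t1"],
                                 pts["year_t0"], pts["year_t1"])
    clean = clean_records(pts)
    metrics = pts.join(clean.flags)
    return metrics, models, clean
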