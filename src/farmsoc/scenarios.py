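"""Per-zone management effects and continental scenario upscaling.

The *management effect* of a pedoclimatic zone × land-use stratum is
the difference in mean observed SOC stock between the 10% of its points
with the best and the 10% with the worst management, where "best" is
ranked by the fixed-effect linear predictor of the fitted mixed model
evaluated on the management terms only (the zone intercept is excluded
so ranking reflects management, not pedoclimate).

The *option space* upscales these deciles to carbon totals: per
stratum, the best-case (worst-case) change is the difference between
the top-decile (bottom-decile) mean stock and the stratum mean stock,
multiplied by the stratum area; totals are reported in Pg C
(1 Pg = 10⁹ Mg). Standard errors of decile and stratum means are
combined assuming independence and propagated through the area
weighting with the usual variance formula, giving symmetric 95%
confidence intervals.

*Management variability* of a zone is the mean, across indicators, of
the within-zone standard deviation of the dataset-wide min–max
normalised indicator: zones where even small management contrasts
produce significant effects mark particularly sensitive soils.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices

from .effects import FitResult, term_variables

MG_PER_PG = 1e9
DEFAULT_DECILE = 0.10
MIN_STRATUM_POINTS = 20


def rank_by_optimality(points: pd.DataFrame, fit: FitResult,
                       management_terms: tuple[str, ...] | None = None) -> pd.Series:
    """Score points by expected SOC benefit of their management.

    The score is Xβ restricted to the management fixed-effect columns
    (all non-intercept terms by default); higher means better expected
    SOC. Points with missing management get NaN and are excluded from
    deciles. Ties are broken deterministically by point order later.
    """
    if management_terms is None:
        management_terms = tuple(t for t in fit.terms)
    needed = sorted(set().union(*(term_variables(t) for t in management_terms))) \
        if management_terms else []
    ok = points[needed].notna().all(axis=1) if needed else pd.Series(True, index=points.index)
    scores = pd.Series(np.nan, index=points.index, dtype=float)
    if not ok.any():
        return scores
    di = fit.result.model.data.design_info
    (x,) = build_design_matrices([di], points.loc[ok])
    x = np.asarray(x)
    names = list(fit.fe_params.index)
    keep = np.zeros(len(names), dtype=bool)
    for term, sl in di.term_name_slices.items():
        if term in management_terms:
            keep[sl] = True
    beta = fit.fe_params.to_numpy() * keep
    scores.loc[ok] = x @ beta
    return scores


@dataclass
class ZoneEffect:
    """Decile management effect of one zone × land-use stratum."""

    zone: str
    land_use: str
    n_points: int
    top_mean: float
    bottom_mean: float
    stratum_mean: float
    se_top: float
    se_bottom: float
    se_mean: float
    effect: float
    se_effect: float
    variability: float = float("nan")


def _decile_mean(stocks: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(stocks))
    se = float(np.std(stocks, ddof=1) / np.sqrt(len(stocks))) if len(stocks) > 1 else 0.0
    return m, se


def management_effect(stocks, scores, point_ids=None,
                      q: float = DEFAULT_DECILE,
                      min_points: int = MIN_STRATUM_POINTS) -> dict | None:
    """Top-decile minus bottom-decile mean stock within one stratum.

    Points are ordered by score (ties broken by point id); the decile
    size is ⌈q·n⌉. Returns None when fewer than ``min_points`` scored
    points are available.
    """
    s = np.asarray(stocks, dtype=float)
    sc = np.asarray(scores, dtype=float)
    ids = np.asarray(point_ids) if point_ids is not None else np.arange(len(s))
    ok = ~(np.isnan(s) | np.isnan(sc))
    s, sc, ids = s[ok], sc[ok], ids[ok]
    n = len(s)
    if n < min_points:
        return None
    order = np.lexsort((ids, -sc))  # best first, deterministic ties
    m = int(np.ceil(q * n))
    top, bottom = s[order[:m]], s[order[-m:]]
    top_mean, se_top = _decile_mean(top)
    bottom_mean, se_bottom = _decile_mean(bottom)
    stratum_mean, se_mean = _decile_mean(s)
    return {
        "n_points": n, "decile_size": m,
        "top_mean": top_mean, "bottom_mean": bottom_mean,
        "stratum_mean": stratum_mean,
        "se_top": se_top, "se_bottom": se_bottom, "se_mean": se_mean,
        "effect": top_mean - bottom_mean,
        "se_effect": float(np.hypot(se_top, se_bottom)),
    }


def management_variability(zone_values: pd.DataFrame,
                           dataset_values: pd.DataFrame) -> float:
    """Mean normalised within-zone SD of the management indicators.

    Each shared numeric column is min–max normalised over the whole
    dataset; the zone's SD of each normalised indicator is averaged
    (indicators missing throughout the zone are skipped). A uniformly
    spread indicator contributes about 1/√12 ≈ 0.289.
    """
    sds = []
    for c in dataset_values.columns:
        full = dataset_values[c].astype(float)
        lo, hi = full.min(), full.max()
        if not np.isfinite(lo) or hi == lo:
            continue
        z = (zone_values[c].astype(float) - lo) / (hi - lo)
        z = z.dropna()
        if len(z) >= 2:
            sds.append(float(z.std(ddof=1)))
    return float(np.mean(sds)) if sds else float("nan")


def zone_effects(points: pd.DataFrame, fit: FitResult,
                 indicator_cols: list[str],
                 stock_col: str = "stock",
                 management_terms: tuple[str, ...] | None = None,
                 q: float = DEFAULT_DECILE,
                 min_points: int = MIN_STRATUM_POINTS) -> pd.DataFrame:
    """Management effect and variability per zone × land-use stratum."""
    scores = rank_by_optimality(points, fit, management_terms)
    rows = []
    for (zone, lu), sub in points.groupby(["zone", "land_use"], observed=True):
        eff = management_effect(sub[stock_col], scores.loc[sub.index],
                                sub["point_id"], q=q, min_points=min_points)
        if eff is None:
            continue
        eff["variability"] = management_variability(
            sub[indicator_cols], points[indicator_cols])
        rows.append({"zone": zone, "land_use": lu, **eff})
    return pd.DataFrame(rows)


@dataclass
class ScenarioResult:
    """Best/worst-management carbon totals with uncertainty."""

    strata: pd.DataFrame     # per zone × land use, Mg C and Pg C
    totals: pd.DataFrame     # per land use and overall, Pg C with 95% CI
    missing_area: pd.DataFrame  # strata with an effect but no area


def option_space(effects: pd.DataFrame, areas: pd.DataFrame,
                 baseline: str = "stratum_mean",
                 ci: float = 0.95) -> ScenarioResult:
    """Upscale per-stratum decile effects to continental carbon totals.

    ``baseline`` selects the scenario reference: ``"stratum_mean"``
    (default) measures each decile against the stratum's mean stock,
    allowing asymmetric best/worst totals; ``"opposite_decile"``
    measures the two deciles against each other.
    """
    if baseline not in ("stratum_mean", "opposite_decile"):
        raise ValueError(f"unknown baseline {baseline!r}")
    merged = effects.merge(areas[["zone", "land_use", "area_ha"]],
                           on=["zone", "land_use"], how="left")
    missing = merged[merged["area_ha"].isna()].copy()
    strata = merged.dropna(subset=["area_ha"]).copy()

    if baseline == "stratum_mean":
        strata["best_per_ha"] = strata["top_mean"] - strata["stratum_mean"]
        strata["worst_per_ha"] = strata["bottom_mean"] - strata["stratum_mean"]
        strata["se_best"] = np.hypot(strata["se_top"], strata["se_mean"])
        strata["se_worst"] = np.hypot(strata["se_bottom"], strata["se_mean"])
    else:
        strata["best_per_ha"] = strata["top_mean"] - strata["bottom_mean"]
        strata["worst_per_ha"] = strata["bottom_mean"] - strata["top_mean"]
        strata["se_best"] = strata["se_effect"]
        strata["se_worst"] = strata["se_effect"]

    for side in ("best", "worst"):
        strata[f"{side}_mg"] = strata[f"{side}_per_ha"] * strata["area_ha"]
        strata[f"{side}_pg"] = strata[f"{side}_mg"] / MG_PER_PG
        strata[f"se_{side}_mg"] = strata[f"se_{side}"] * strata["area_ha"]

    from scipy.stats import norm
    z = norm.ppf(0.5 + ci / 2)
    rows = []
    groups = [(lu, sub) for lu, sub in strata.groupby("land_use", observed=True)]
    groups.append(("all", strata))
    for lu, sub in groups:
        rec = {"land_use": lu, "area_ha": float(sub["area_ha"].sum())}
        for side in ("best", "worst"):
            total = float(sub[f"{side}_mg"].sum()) / MG_PER_PG
            se = float(np.sqrt(np.sum(sub[f"se_{side}_mg"] ** 2))) / MG_PER_PG
            rec[f"{side}_pg"] = total
            rec[f"{side}_se_pg"] = se
            rec[f"{side}_ci_low"] = total - z * se
            rec[f"{side}_ci_high"] = total + z * se
        rows.append(rec)
    totals = pd.DataFrame(rows)
    return ScenarioResult(strata=strata, totals=totals, missing_area=missing)
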