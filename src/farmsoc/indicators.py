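"""Per-farm management indicators from survey microdata.

The indicators summarise the fertilisation regime, rotation structure and
tillage of a single farm-year:

* N, P, K nutrient input (kg ha⁻¹): mineral fertiliser plus animal-based
  input, the latter derived from livestock density times a per-livestock-
  unit excretion table (defaults for one standard livestock unit, i.e.
  one dairy cow: 135 kg N, 19 kg P, 139 kg K per year).
* Share of manure in the fertiliser mix per nutrient.
* Crop-rotational diversity: Gini–Simpson index of arable crop areas.
* Crop-rotational composition: share of each rotation category of the
  arable area, plus crop richness (number of arable crops grown).
* Tillage intensity: conventional tillage weighted 1, conservation
  tillage 0.2, zero tillage 0, joined to farms through the region ×
  farm-size × farm-type cell of an aggregate tillage-area table.

All functions accept scalars or numpy arrays and are used both row-wise
in tests and vectorised over whole survey tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crops import ARABLE, CATEGORIES, Crop, DEFAULT_CROPS

NUTRIENTS = ("n", "p", "k")

ALTITUDE_LABELS = ("<300", "300-600", ">600")


@dataclass(frozen=True)
class ExcretionTable:
    """Annual nutrient excretion per livestock unit (kg LU⁻¹ yr⁻¹)."""

    n_kg: float = 135.0
    p_kg: float = 19.0
    k_kg: float = 139.0

    def __post_init__(self) -> None:
        for nut in NUTRIENTS:
            if getattr(self, f"{nut}_kg") < 0:
                raise ValueError(f"excretion {nut}_kg must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {nut: getattr(self, f"{nut}_kg") for nut in NUTRIENTS}


DEFAULT_EXCRETION = ExcretionTable()


def altitude_class(altitude_m, breaks=(300.0, 600.0)):
    """Classify altitude (m a.s.l.) into the three survey altitude zones."""
    lo, hi = breaks
    if not lo < hi:
        raise ValueError("altitude breaks must be strictly increasing")
    alt = np.asarray(altitude_m, dtype=float)
    out = np.where(alt < lo, ALTITUDE_LABELS[0],
                   np.where(alt <= hi, ALTITUDE_LABELS[1], ALTITUDE_LABELS[2]))
    return out.item() if np.isscalar(altitude_m) else out


def nutrient_input(uaa_ha, livestock_units, mineral_kg: dict,
                   excretion: ExcretionTable = DEFAULT_EXCRETION) -> dict:
    """Total N, P, K input in kg ha⁻¹ (mineral + animal-based).

    Animal-based input per nutrient is livestock density (LU ha⁻¹) times
    the per-LU excretion. ``mineral_kg`` maps nutrient -> total mineral
    fertiliser in kg (whole farm, not per ha).
    """
    uaa = np.asarray(uaa_ha, dtype=float)
    if np.any(uaa <= 0):
        raise ValueError("uaa_ha must be > 0 for nutrient input")
    lu_density = np.asarray(livestock_units, dtype=float) / uaa
    exc = excretion.as_dict()
    return {nut: np.asarray(mineral_kg[nut], dtype=float) / uaa + lu_density * exc[nut]
            for nut in NUTRIENTS}


def manure_share(uaa_ha, livestock_units, mineral_kg: dict,
                 excretion: ExcretionTable = DEFAULT_EXCRETION) -> dict:
    """Animal-based share of total nutrient input per nutrient.

    NaN where the total input of a nutrient is zero.
    """
    uaa = np.asarray(uaa_ha, dtype=float)
    exc = excretion.as_dict()
    out = {}
    for nut in NUTRIENTS:
        animal = np.asarray(livestock_units, dtype=float) * exc[nut]
        mineral = np.asarray(mineral_kg[nut], dtype=float)
        total = animal + mineral
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(total > 0, animal / np.where(total > 0, total, 1.0), np.nan)
        out[nut] = share.item() if share.ndim == 0 else share
    return out


def rotation_diversity(arable_areas) -> float:
    """Gini–Simpson index 1 − Σ pᵢ² of arable crop area shares.

    NaN when the total arable area is zero; 0 for a monoculture; the
    upper bound for k crops is 1 − 1/k.
    """
    areas = np.asarray(arable_areas, dtype=float)
    areas = areas[areas > 0]
    total = areas.sum()
    if total <= 0:
        return float("nan")
    p = areas / total
    return float(1.0 - np.sum(p * p))


def crop_composition(crop_areas: dict, cat_map: dict) -> dict:
    """Rotation-category shares of the arable area plus crop richness.

    Returns a dict with one ``share_<category>`` entry per category,
    ``ley_share``, ``fodder_legume_share``, ``ley_fodder_share`` and
    ``crop_richness``. Shares are NaN when the farm has no arable area.
    Unmapped crop codes raise ``KeyError`` listing the codes.
    """
    unknown = [c for c in crop_areas if c not in cat_map]
    if unknown:
        raise KeyError(f"crop codes without a category mapping: {sorted(unknown)}")
    cat_area = dict.fromkeys(CATEGORIES, 0.0)
    richness = 0
    for code, area in crop_areas.items():
        cat = cat_map[code]
        if cat is None or area <= 0:
            continue
        cat_area[cat] += float(area)
        richness += 1
    arable_total = sum(cat_area.values())
    out = {}
    for cat in CATEGORIES:
        out[f"share_{cat}"] = cat_area[cat] / arable_total if arable_total > 0 else float("nan")
    out["ley_share"] = out["share_leys"]
    out["fodder_legume_share"] = out["share_fodder_legumes"]
    out["ley_fodder_share"] = (out["share_leys"] + out["share_fodder_legumes"]
                               if arable_total > 0 else float("nan"))
    out["crop_richness"] = richness
    return out


def tillage_intensity(conventional_ha, conservation_ha, zero_ha):
    """Area-weighted tillage intensity of a tillage-table cell.

    Conventional tillage counts 1, conservation tillage 0.2, zero
    tillage 0. NaN where the cell has no area.
    """
    conv = np.asarray(conventional_ha, dtype=float)
    cons = np.asarray(conservation_ha, dtype=float)
    zero = np.asarray(zero_ha, dtype=float)
    if np.any(conv < 0) or np.any(cons < 0) or np.any(zero < 0):
        raise ValueError("tillage areas must be >= 0")
    total = conv + cons + zero
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (conv * 1.0 + cons * 0.2) / np.where(total > 0, total, 1.0),
                       np.nan)
    return out.item() if out.ndim == 0 else out


def _area_columns(farms: pd.DataFrame) -> list[str]:
    return [c for c in farms.columns if c.startswith("area_")]


def compute_indicators(farms: pd.DataFrame,
                       crops: tuple[Crop, ...] = DEFAULT_CROPS,
                       excretion: ExcretionTable = DEFAULT_EXCRETION,
                       tillage: pd.DataFrame | None = None) -> pd.DataFrame:
    """Compute all management indicators for a survey table.

    ``farms`` is one row per farm-year with ``area_<crop>`` columns; the
    optional ``tillage`` table has one row per (region, size_class,
    farm_type) cell with conventional/conservation/zero areas. Farms
    whose cell is absent get a missing tillage intensity.
    """
    cat_map = {c.code: c.category for c in crops}
    arable = [c.code for c in crops if c.land_use == ARABLE]
    area_cols = _area_columns(farms)
    codes = [c.removeprefix("area_") for c in area_cols]
    unknown = [c for c in codes if c not in cat_map]
    if unknown:
        raise KeyError(f"crop codes without a category mapping: {sorted(unknown)}")

    out = farms[["farm_id", "year", "region", "country", "altitude_class",
                 "farm_type", "size_class", "uaa_ha", "organic",
                 "livestock_units"]].copy()
    mineral = {nut: farms[f"mineral_{nut}_kg"] for nut in NUTRIENTS}
    inputs = nutrient_input(farms["uaa_ha"], farms["livestock_units"], mineral, excretion)
    shares = manure_share(farms["uaa_ha"], farms["livestock_units"], mineral, excretion)
    for nut in NUTRIENTS:
        out[f"{nut}_input"] = inputs[nut]
        out[f"manure_share_{nut}"] = shares[nut]

    arable_cols = [f"area_{c}" for c in arable if f"area_{c}" in farms.columns]
    arable_mat = farms[arable_cols].to_numpy(dtype=float)
    arable_mat = np.where(arable_mat > 0, arable_mat, 0.0)
    totals = arable_mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = arable_mat / np.where(totals > 0, totals, 1.0)[:, None]
    gini = np.where(totals > 0, 1.0 - (p * p).sum(axis=1), np.nan)
    out["rotation_diversity"] = gini
    out["crop_richness"] = (arable_mat > 0).sum(axis=1)

    # category shares of arable area
    for cat in CATEGORIES:
        cols = [f"area_{c}" for c in arable if cat_map[c] == cat and f"area_{c}" in farms.columns]
        cat_sum = farms[cols].to_numpy(dtype=float).clip(min=0).sum(axis=1) if cols else np.zeros(len(farms))
        out[f"share_{cat}"] = np.where(totals > 0, cat_sum / np.where(totals > 0, totals, 1.0), np.nan)
    out["ley_share"] = out["share_leys"]
    out["fodder_legume_share"] = out["share_fodder_legumes"]
    out["ley_fodder_share"] = out["share_leys"] + out["share_fodder_legumes"]

    if tillage is not None:
        cells = tillage.copy()
        cells["tillage_intensity"] = tillage_intensity(
            cells["conventional_ha"], cells["conservation_ha"], cells["zero_ha"])
        out = out.merge(
            cells[["region", "size_class", "farm_type", "tillage_intensity"]],
            on=["region", "size_class", "farm_type"], how="left")
    else:
        out["tillage_intensity"] = np.nan
    return out
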