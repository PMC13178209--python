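"""Rank-based management-intensity composite.

Each management variable is ranked across the whole analysis set
(average ranks for ties, missing values retained), min–max rescaled to
[0, 1] on the non-missing values, and reversed for practices that lower
intensity (organic probability, manure shares, crop diversity and
richness, ley/fodder share). Variables measured by several indicators —
nutrient input (N, P, K), manure share (N, P, K) and crop diversity
(Gini–Simpson plus richness) — are grouped so that each management
function contributes unit weight on average, with equal weight for the
constituents of a group. The intensity index of a point is the weighted
mean over its non-missing groups and therefore lives in [0, 1]; it is
missing only when every variable is missing.

Because the index is built on ranks, any strictly monotone transform of
a raw variable leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IntensityGroup:
    """One management function: constituent columns and rank direction."""

    name: str
    columns: tuple[str, ...]
    reverse: bool          # True: practice lowers intensity, rank descending
    weight: float = 1.0


@dataclass(frozen=True)
class IntensitySpec:
    groups: tuple[IntensityGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("intensity spec needs at least one group")
        for g in self.groups:
            if g.weight <= 0:
                raise ValueError(f"group {g.name!r} has non-positive weight")


#: Default composite over predicted management medians at soil points.
DEFAULT_INTENSITY_SPEC = IntensitySpec(groups=(
    IntensityGroup("nutrient_input", ("n_input_med", "p_input_med", "k_input_med"),
                   reverse=False),
    IntensityGroup("manure_share", ("manure_share_n_med", "manure_share_p_med",
                                    "manure_share_k_med"), reverse=True),
    IntensityGroup("organic", ("organic_probability",), reverse=True),
    IntensityGroup("crop_diversity", ("rotation_diversity_med", "crop_richness_med"),
                   reverse=True),
    IntensityGroup("ley_fodder", ("ley_fodder_share_med",), reverse=True),
    IntensityGroup("tillage", ("tillage_intensity_med",), reverse=False),
))


def rank_normalize(values, reverse: bool = False) -> pd.Series:
    """Average-tie ranks min–max rescaled to [0, 1], missing preserved.

    ``reverse=True`` ranks descending, so the largest raw value maps to
    0. A constant (or single-valued) variable maps to 0.5 everywhere —
    the midpoint avoids manufacturing extremes out of no information.
    """
    s = pd.Series(values, dtype=float)
    ranks = s.rank(method="average", ascending=not reverse)
    lo, hi = ranks.min(), ranks.max()
    if not np.isfinite(lo):      # all missing
        return ranks
    if hi == lo:
        return ranks.where(ranks.isna(), 0.5)
    return (ranks - lo) / (hi - lo)


def compose_intensity(table: pd.DataFrame,
                      spec: IntensitySpec = DEFAULT_INTENSITY_SPEC) -> pd.DataFrame:
    """Normalized ranks per variable plus the composite intensity index.

    Returns a frame with one ``rank_<column>`` per constituent, one
    ``group_<name>`` per group (mean of its non-missing constituents)
    and the ``intensity`` column: the weighted mean over non-missing
    groups.
    """
    out = pd.DataFrame(index=table.index)
    group_vals = {}
    for g in spec.groups:
        missing_cols = [c for c in g.columns if c not in table.columns]
        if missing_cols:
            raise KeyError(f"intensity group {g.name!r} references absent "
                           f"columns {missing_cols}")
        ranks = pd.DataFrame(
            {c: rank_normalize(table[c], reverse=g.reverse) for c in g.columns})
        for c in g.columns:
            out[f"rank_{c}"] = ranks[c]
        gv = ranks.mean(axis=1, skipna=True)
        out[f"group_{g.name}"] = gv
        group_vals[g.name] = (gv, g.weight)

    vals = pd.DataFrame({name: gv for name, (gv, _) in group_vals.items()})
    weights = np.array([w for _, (_, w) in group_vals.items()])
    present = vals.notna().to_numpy()
    num = np.nansum(vals.to_numpy() * weights, axis=1)
    den = (present * weights).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["intensity"] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out
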