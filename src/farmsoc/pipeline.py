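"""End-to-end orchestration of the synthetic study.

``run_all`` executes the stages in dependency order — simulate →
indicators → management prediction → SOC metrics → intensity → mixed
models → scenarios — validating each table against its schema, logging
row counts after every filter, and writing a manifest with checksums so
reruns under the same seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .effects import ModelSpec, backward_eliminate, lrt_vs_null, marginal_effects
from .indicators import compute_indicators
from .intensity import DEFAULT_INTENSITY_SPEC, compose_intensity
from .predict import predict_at_points, within_region_kw_test
from .schemas import require_valid
from .scenarios import option_space, zone_effects
from .soc import compute_soc_metrics
from .synth import Simulation, SynthConfig, simulate, write_simulation

log = logging.getLogger("farmsoc")

#: management variables behind the per-zone variability summary
VARIABILITY_INDICATORS = [
    "n_input_med", "p_input_med", "k_input_med",
    "manure_share_n_med", "manure_share_p_med", "manure_share_k_med",
    "organic_probability", "rotation_diversity_med", "crop_richness_med",
    "ley_fodder_share_med", "tillage_intensity_med",
]

INTENSITY_MODEL_TERMS = ("intensity", "C(land_use)", "intensity:C(land_use)")
PRACTICE_MODEL_TERMS = (
    "manure_share_n_med", "organic_probability",
    "n_input_med", "I(n_input_med**2)", "C(land_use)")
PRACTICE_ARABLE_TERMS = (
    "manure_share_n_med", "organic_probability",
    "n_input_med", "I(n_input_med**2)",
    "rotation_diversity_med", "ley_fodder_share_med", "tillage_intensity_med")


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters of a full run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    min_group_size: int = 15
    elimination_alpha: float = 0.05
    decile_q: float = 0.10
    min_bd_points: int = 30
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be positive")
        if not 0 < self.decile_q < 0.5:
            raise ValueError("decile_q must be in (0, 0.5)")
        if not 0 < self.elimination_alpha < 1:
            raise ValueError("elimination_alpha must be in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, out: Path, name: str, manifest: dict) -> None:
    path = out / f"{name}.csv"
    df.to_csv(path, index=False)
    manifest["outputs"][name] = {"rows": int(len(df)), "sha256": _sha256(path)}
    log.info("%s: %d rows -> %s", name, len(df), path)


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write all outputs and return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "farmsoc_version": __version__,
        "seed": config.synth.seed,
        "outputs": {},
        "stage_log": {},
    }

    sim: Simulation = simulate(config.synth)
    for name, table in [("farms", sim.farms), ("tillage", sim.tillage),
                        ("points", sim.points), ("benchmarks", sim.benchmarks)]:
        require_valid(table, name)
    write_simulation(sim, out)
    for name, df in [("farms", sim.farms), ("tillage", sim.tillage),
                     ("points", sim.points), ("benchmarks", sim.benchmarks),
                     ("ground_truth", sim.ground_truth.points),
                     ("regions", sim.regions)]:
        manifest["outputs"][name] = {
            "rows": int(len(df)), "sha256": _sha256(out / f"{name}.csv")}

    indicators = compute_indicators(sim.farms, config.synth.crops,
                                    config.synth.excretion, sim.tillage)
    _write(indicators, out, "farm_indicators", manifest)

    predicted = predict_at_points(sim.points, sim.farms, indicators,
                                  min_group_size=config.min_group_size,
                                  region_centroids=sim.regions,
                                  crops=config.synth.crops)
    require_valid(predicted, "predicted_management")
    tiers = predicted["tier"].value_counts(normalize=True).round(4).to_dict()
    manifest["stage_log"]["tier_fractions"] = tiers
    _write(predicted, out, "predicted_management", manifest)

    # added-value check: does the crop x altitude grouping separate
    # farm-level management within regions?
    group_key = sim.farms["altitude_class"].astype(str) + "|" + sim.farms["farm_type"]
    kw_in = indicators.assign(group=group_key.to_numpy())
    kw, pct = within_region_kw_test(kw_in, "n_input")
    manifest["stage_log"]["kw_pct_significant_n_input"] = pct
    _write(kw, out, "kw_tests", manifest)

    metrics, bd_models, clean = compute_soc_metrics(
        sim.points, sim.benchmarks, min_bd_points=config.min_bd_points,
        zone_seed=config.synth.seed)
    require_valid(metrics, "soc_metrics")
    manifest["stage_log"]["cleaning"] = clean.counts
    manifest["stage_log"]["bd_models"] = {
        lu: {"terms": list(m.terms), "aic": m.aic, "n": m.n}
        for lu, m in bd_models.items()}
    _write(metrics, out, "soc_metrics", manifest)

    intensity = compose_intensity(predicted, DEFAULT_INTENSITY_SPEC)
    intensity.insert(0, "point_id", predicted["point_id"])
    require_valid(intensity, "intensity")
    _write(intensity, out, "intensity", manifest)

    analysis = (metrics.merge(predicted, on="point_id")
                .merge(intensity[["point_id", "intensity"]], on="point_id"))
    stock_set = analysis[~analysis["removed_organic"]]

    fits = {}
    summaries = []
    for name, terms, data in [
            ("intensity", INTENSITY_MODEL_TERMS, stock_set),
            ("practices", PRACTICE_MODEL_TERMS, stock_set),
            ("practices_arable", PRACTICE_ARABLE_TERMS,
             stock_set[stock_set["land_use"] == "arable"])]:
        spec = ModelSpec(response="stock", transform="log1p", fixed_terms=terms,
                         group="zone", alpha=config.elimination_alpha)
        try:
            fit = backward_eliminate(data, spec)
        except ValueError as exc:
            log.warning("model %s skipped: %s", name, exc)
            continue
        chi2, p = lrt_vs_null(fit)
        fits[name] = fit
        frame = fit.summary_frame().reset_index(names="term")
        frame.insert(0, "model", name)
        summaries.append(frame)
        manifest["stage_log"][f"model_{name}"] = {
            "terms": list(fit.terms), "n": fit.n, "chi2": chi2, "p": p}
    if summaries:
        _write(pd.concat(summaries, ignore_index=True), out, "model_coefficients",
               manifest)
    if "intensity" in fits and any("intensity" in t for t in fits["intensity"].terms):
        me = marginal_effects(fits["intensity"], "intensity", by="land_use")
        _write(me, out, "marginal_effects_intensity", manifest)

    if "practices" in fits:
        effects = zone_effects(stock_set, fits["practices"],
                               indicator_cols=[c for c in VARIABILITY_INDICATORS
                                               if c in stock_set.columns],
                               q=config.decile_q)
        _write(effects, out, "zone_effects", manifest)
        result = option_space(effects, sim.benchmarks)
        _write(result.strata, out, "scenario_strata", manifest)
        _write(result.totals, out, "scenarios", manifest)
        manifest["stage_log"]["option_space_pg"] = {
            row["land_use"]: {"best": row["best_pg"], "worst": row["worst_pg"]}
            for _, row in result.totals.iterrows()}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
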