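"""Column schemas and validation for the pipeline's CSV interfaces.

Each stage output has a registered schema: required columns with a type
kind and an optional closed value range. Validation reports missing
columns, type mismatches and range violations as errors; unknown extra
columns are a warning only, so downstream additions never break
producers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Column:
    name: str
    kind: str                      # "str" | "float" | "int" | "bool"
    range: tuple[float, float] | None = None
    required: bool = True


@dataclass
class ValidationReport:
    table: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class SchemaError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(
            f"schema {report.table!r}: " + "; ".join(report.errors))


SCHEMAS: dict[str, list[Column]] = {
    "farms": [
        Column("farm_id", "str"),
        Column("year", "int"),
        Column("region", "str"),
        Column("country", "str"),
        Column("altitude_class", "str"),
        Column("farm_type", "str"),
        Column("size_class", "str"),
        Column("uaa_ha", "float", (1e-9, np.inf)),
        Column("organic", "bool"),
        Column("livestock_units", "float", (0, np.inf)),
        Column("mineral_n_kg", "float", (0, np.inf)),
        Column("mineral_p_kg", "float", (0, np.inf)),
        Column("mineral_k_kg", "float", (0, np.inf)),
    ],
    "tillage": [
        Column("region", "str"),
        Column("size_class", "str"),
        Column("farm_type", "str"),
        Column("conventional_ha", "float", (0, np.inf)),
        Column("conservation_ha", "float", (0, np.inf)),
        Column("zero_ha", "float", (0, np.inf)),
    ],
    "points": [
        Column("point_id", "str"),
        Column("lon", "float", (-180, 180)),
        Column("lat", "float", (-90, 90)),
        Column("region", "str"),
        Column("country", "str"),
        Column("altitude_m", "float", (-500, 9000)),
        Column("altitude_class", "str"),
        Column("land_cover", "str"),
        Column("land_use", "str"),
        Column("land_use_t0", "str", required=False),
        Column("oc_t0", "float", (0, np.inf)),
        Column("oc_t1", "float", (0, np.inf)),
        Column("year_t0", "int"),
        Column("year_t1", "int"),
        Column("bd_measured", "float", (0.05, 2.8), required=False),
        Column("coarse_frag", "float", (0, 1)),
        Column("sand", "float", (0, 100)),
        Column("clay", "float", (0, 100)),
        Column("ph", "float", (2, 11)),
        Column("total_n", "float", (0, np.inf)),
        Column("map_mm", "float", (0, np.inf)),
        Column("zone", "str", required=False),
    ],
    "benchmarks": [
        Column("zone", "str"),
        Column("land_use", "str"),
        Column("typical_stock", "float", (1e-9, np.inf)),
        Column("area_ha", "float", (0, np.inf)),
    ],
    "predicted_management": [
        Column("point_id", "str"),
        Column("tier", "str"),
        Column("n_farms", "int"),
        Column("organic_probability", "float", (0, 1), required=False),
    ],
    "soc_metrics": [
        Column("point_id", "str"),
        Column("bd_ref", "float", (0.05, 2.8)),
        Column("stock", "float", (0, np.inf)),
        Column("benchmark_ratio", "float", (0, np.inf), required=False),
        Column("delta_soc", "float"),
        Column("removed_organic", "bool"),
        Column("removed_landuse_change", "bool"),
        Column("removed_delta_outlier", "bool"),
    ],
    "intensity": [
        Column("point_id", "str"),
        Column("intensity", "float", (0, 1), required=False),
    ],
}

_KIND_CHECKS = {
    "float": lambda s: pd.api.types.is_numeric_dtype(s),
    "int": lambda s: pd.api.types.is_integer_dtype(s) or pd.api.types.is_float_dtype(s),
    "str": lambda s: s.dtype == object or pd.api.types.is_string_dtype(s)
    or isinstance(s.dtype, pd.CategoricalDtype),
    "bool": lambda s: pd.api.types.is_bool_dtype(s) or s.dropna().isin(
        [True, False, 0, 1]).all(),
}


def validate_schema(table: pd.DataFrame, schema_name: str) -> ValidationReport:
    """Check a table against a registered schema."""
    if schema_name not in SCHEMAS:
        raise KeyError(f"no schema registered under {schema_name!r}")
    schema = SCHEMAS[schema_name]
    report = ValidationReport(table=schema_name)
    known = {c.name for c in schema}
    for col in schema:
        if col.name not in table.columns:
            if col.required:
                report.errors.append(f"missing required column {col.name!r}")
            continue
        s = table[col.name]
        if not _KIND_CHECKS[col.kind](s):
            report.errors.append(
                f"column {col.name!r} has dtype {s.dtype}, expected {col.kind}")
            continue
        if col.range is not None and col.kind in ("float", "int"):
            vals = pd.to_numeric(s, errors="coerce").dropna()
            lo, hi = col.range
            bad = int(((vals < lo) | (vals > hi)).sum())
            if bad:
                report.errors.append(
                    f"column {col.name!r}: {bad} values outside [{lo}, {hi}]")
    extra = [c for c in table.columns if c not in known
             and not c.startswith(("area_", "share_"))
             and not c.endswith(("_med", "_sd"))]
    if extra:
        report.warnings.append(f"unrecognised extra columns {extra}")
    return report


def require_valid(table: pd.DataFrame, schema_name: str) -> None:
    """Raise ``SchemaError`` if the table fails validation."""
    report = validate_schema(table, schema_name)
    if not report.ok:
        raise SchemaError(report)
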