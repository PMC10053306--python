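"""CSV/JSON readers and writers and run configuration.

Canonical on-disk form is a long-format CSV with columns
``response_label, power_w, time_min, value, units`` (one row per
observation). A wide form — ``time_min`` plus one numeric column per
irradiation power — is accepted read-only. All floating-point rendering is
locale-independent ('.' decimal, RFC-4180 CSV, UTF-8).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import FitOptions, KineticDataset
from .gof import DISPLAY_DECIMALS, ComparisonTable, round_display
from .models import MODEL_ORDER
from .power_profile import SplineOptimum

__all__ = [
    "KineticsValidationError",
    "RunConfig",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "write_report",
    "read_run_config",
]

logger = logging.getLogger("maekin")

LONG_COLUMNS = ["response_label", "power_w", "time_min", "value", "units"]


class KineticsValidationError(ValueError):
    """Input data failed validation; message names the offending group/row."""


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration for a pipeline run."""

    input_path: Optional[str] = None
    output_path: Optional[str] = None
    models: tuple[str, ...] = MODEL_ORDER
    fit_options: FitOptions = field(default_factory=FitOptions)
    render_decimals: dict = field(default_factory=lambda: dict(DISPLAY_DECIMALS))
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "models", tuple(self.models))
        if not self.models:
            raise ValueError("RunConfig: model selection must be non-empty")
        unknown = [m for m in self.models if m not in MODEL_ORDER]
        if unknown:
            raise ValueError(f"RunConfig: unknown models {unknown}")


def read_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    fit_raw = raw.pop("fit_options", {})
    return RunConfig(fit_options=FitOptions(**fit_raw), **raw)


def _dataset_from_group(label: str, power, sub: pd.DataFrame) -> KineticDataset:
    group = f"{label}/{power if power is not None else 'no-power'}"
    sub = sub.sort_values("time_min")
    times = sub["time_min"].to_numpy(dtype=float)
    values = sub["value"].to_numpy(dtype=float)
    units = ""
    if "units" in sub.columns and sub["units"].notna().any():
        units = str(sub["units"].dropna().iloc[0])
    try:
        return KineticDataset(times=times, values=values, response_label=label,
                              power_w=None if power is None else float(power),
                              units=units)
    except ValueError as exc:
        raise KineticsValidationError(f"group {group}: {exc}") from exc


def read_kinetics_csv(path: str | Path) -> list[KineticDataset]:
    """Read one validated dataset per (response_label, power) group.

    Long format is detected by the presence of ``value`` and
    ``response_label`` columns; anything else with a ``time_min`` column is
    treated as wide (one power per numeric column header). Missing or
    non-numeric entries are rejected with row-numbered messages.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise KineticsValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = set(df.columns)
    if {"response_label", "time_min", "value"} <= cols:
        return _read_long(df)
    if "time_min" in cols and len(cols) >= 2:
        return _read_wide(df)
    raise KineticsValidationError(
        f"{path}: unrecognized header {sorted(cols)}; expected long format "
        f"{LONG_COLUMNS} or wide format (time_min + power columns)")


def _require_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    num = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[num.isna()].tolist()
    if bad:
        raise KineticsValidationError(
            f"column {col!r}: missing or non-numeric values at CSV rows "
            f"{[i + 2 for i in bad[:5]]}")  # +2: header + 1-based
    return num


def _read_long(df: pd.DataFrame) -> list[KineticDataset]:
    df = df.copy()
    df["time_min"] = _require_numeric(df, "time_min")
    df["value"] = _require_numeric(df, "value")
    has_power = "power_w" in df.columns and df["power_w"].notna().any()
    datasets = []
    if has_power:
        df["power_w"] = _require_numeric(df, "power_w")
        for (label, power), sub in df.groupby(["response_label", "power_w"], sort=True):
            datasets.append(_dataset_from_group(str(label), power, sub))
    else:
        for label, sub in df.groupby("response_label", sort=True):
            datasets.append(_dataset_from_group(str(label), None, sub))
    return datasets


def _read_wide(df: pd.DataFrame) -> list[KineticDataset]:
    df = df.copy()
    df["time_min"] = _require_numeric(df, "time_min")
    datasets = []
    for col in df.columns:
        if col == "time_min":
            continue
        try:
            power = float(col)
        except ValueError:
            raise KineticsValidationError(
                f"wide format: column header {col!r} is not a numeric power") from None
        values = _require_numeric(df, col)
        sub = pd.DataFrame({"time_min": df["time_min"], "value": values})
        datasets.append(_dataset_from_group("Y", power, sub))
    return datasets


def write_kinetics_csv(datasets: Sequence[KineticDataset], path: str | Path) -> None:
    """Write datasets in canonical long format at full float precision."""
    records = []
    for ds in datasets:
        for t, v in zip(ds.times, ds.values):
            records.append({
                "response_label": ds.response_label,
                "power_w": "" if ds.power_w is None else repr(float(ds.power_w)),
                "time_min": repr(float(t)),
                "value": repr(float(v)),
                "units": ds.units,
            })
    pd.DataFrame.from_records(records, columns=LONG_COLUMNS).to_csv(
        path, index=False, lineterminator="\n")


def _optimum_dict(optimum: Optional[SplineOptimum]) -> dict:
    if optimum is None:
        return {"power_opt_w": None, "k_max": None,
                "at_knot": None, "interval_index": None}
    return {"power_opt_w": optimum.power_opt_w, "k_max": optimum.k_max,
            "at_knot": optimum.at_knot, "interval_index": optimum.interval_index}


def write_report(table: ComparisonTable, optimum: Optional[SplineOptimum],
                 path: str | Path, format: str = "csv") -> None:
    """Render a comparison table (plus optional spline optimum) to disk.

    Values are rounded to the table's printed precision (parameters and R²
    to 3 decimals, SSer to 3, AARD to 2); column order mirrors the printed
    layout (model, power, params..., R², SSer, AARD). Output is
    deterministic: identical inputs give byte-identical files.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"write_report: format must be csv or json, got {format!r}")
    df = table.to_dataframe(rounded=True)
    if format == "csv":
        out = df.copy()
        if optimum is not None:
            out["power_opt_w"] = ""
            out["k_max"] = ""
            out.loc[out.index[0], "power_opt_w"] = repr(optimum.power_opt_w)
            out.loc[out.index[0], "k_max"] = repr(optimum.k_max)
        out.to_csv(path, index=False, lineterminator="\n")
    else:
        payload = {
            "schema_version": 1,
            "rows": json.loads(df.to_json(orient="records")),
            "optimum": _optimum_dict(optimum),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False,
                      default=float)
            fh.write("\n")
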