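"""Goodness-of-fit statistics and per-power × per-model comparison tables.

Three statistics score each fit, all on the original response scale:

* ``SSer``  — sum of squared errors, ``sum((obs - pred)**2)``
* ``R²``    — ``1 - SSer / SStot`` with ``SStot = sum((obs - mean(obs))**2)``
* ``AARD``  — average absolute relative deviation,
  ``(100 / N) * sum(|obs - pred| / obs)`` in percent

A better fit has lower SSer and AARD and higher R². The comparison table
collects the statistics of every (irradiation power, model) pair for one
response and appends per-model mean rows: unweighted arithmetic means over
exactly the powers present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import MODEL_ORDER, MODEL_SPECS

__all__ = [
    "sse",
    "r_squared",
    "aard_pct",
    "ComparisonRow",
    "ComparisonTable",
    "build_comparison_table",
    "round_display",
    "DISPLAY_DECIMALS",
]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if len(obs) < 1:
        raise ValueError("need at least one observation")
    return obs, pred


def sse(observed, predicted) -> float:
    """Sum of squared errors between observed and predicted responses."""
    obs, pred = _pair(observed, predicted)
    return float(np.sum((obs - pred) ** 2))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination about the observed mean; <= 1.

    Undefined (raises) when the observations are all identical.
    """
    obs, pred = _pair(observed, predicted)
    if len(obs) < 2:
        raise ValueError("r_squared: need at least two observations")
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared: undefined for constant observations")
    return 1.0 - sse(obs, pred) / ss_tot


def aard_pct(observed, predicted) -> float:
    """Average absolute relative deviation in percent; observations must be > 0."""
    obs, pred = _pair(observed, predicted)
    if np.any(obs <= 0):
        raise ValueError("aard_pct: all observed values must be > 0")
    return float(100.0 / len(obs) * np.sum(np.abs(obs - pred) / obs))


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

#: printed precision used when rendering reports (internal values stay full)
DISPLAY_DECIMALS = {"params": 3, "r_squared": 3, "sse": 3, "aard_pct": 2}


def round_display(x: float, decimals: int) -> float:
    """Half-up decimal rounding for display (locale-independent)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonRow:
    """Statistics of one model at one irradiation power."""

    power_w: float
    model_id: str
    params: dict[str, float]
    r_squared: float
    sse: float
    aard_pct: float

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_SPECS:
            raise ValueError(f"unknown model_id {self.model_id!r}")


@dataclass(frozen=True)
class MeanRow:
    """Per-model arithmetic means of the statistics across powers."""

    model_id: str
    r_squared: float
    sse: float
    aard_pct: float
    n_powers: int


@dataclass(frozen=True)
class ComparisonTable:
    rows: tuple[ComparisonRow, ...]
    mean_rows: tuple[MeanRow, ...]

    def to_dataframe(self, rounded: bool = False) -> pd.DataFrame:
        """Long-format frame mirroring the printed table layout
        (model, power, params..., R², SSer, AARD) with 'Mean' rows."""
        param_cols: list[str] = []
        for mid in MODEL_ORDER:
            for p in MODEL_SPECS[mid].param_names:
                if p not in param_cols:
                    param_cols.append(p)
        records = []
        for mid in MODEL_ORDER:
            for row in self.rows:
                if row.model_id != mid:
                    continue
                rec = {"model_id": mid, "power_w": row.power_w}
                for p in param_cols:
                    rec[p] = row.params.get(p, np.nan)
                rec.update(r_squared=row.r_squared, sse=row.sse, aard_pct=row.aard_pct)
                records.append(rec)
            for m in self.mean_rows:
                if m.model_id != mid:
                    continue
                rec = {"model_id": mid, "power_w": "Mean"}
                rec.update({p: np.nan for p in param_cols})
                rec.update(r_squared=m.r_squared, sse=m.sse, aard_pct=m.aard_pct)
                records.append(rec)
        df = pd.DataFrame.from_records(
            records, columns=["model_id", "power_w", *param_cols,
                              "r_squared", "sse", "aard_pct"])
        if rounded:
            for p in param_cols:
                df[p] = df[p].map(lambda x: x if pd.isna(x)
                                  else round_display(x, DISPLAY_DECIMALS["params"]))
            for col in ("r_squared", "sse", "aard_pct"):
                df[col] = df[col].map(lambda x: round_display(x, DISPLAY_DECIMALS[
                    col if col in DISPLAY_DECIMALS else "params"]))
        return df


def _rows_from_fits(fits_by_power: Mapping[float, Sequence]) -> list[ComparisonRow]:
    rows = []
    for power, fits in fits_by_power.items():
        for fr in fits:
            rows.append(ComparisonRow(
                power_w=float(power), model_id=fr.model_id,
                params=fr.params_dict, r_squared=fr.r_squared,
                sse=fr.sse, aard_pct=fr.aard_pct))
    return rows


def build_comparison_table(fits) -> ComparisonTable:
    """Assemble the comparison table from fit results grouped by power, or
    from pre-computed :class:`ComparisonRow` records.

    Rows are sorted by (canonical model order, power ascending); duplicate
    (power, model) pairs are rejected. Mean rows average r_squared, sse and
    aard_pct over exactly the powers present for that model.
    """
    if isinstance(fits, Mapping):
        rows = _rows_from_fits(fits)
    else:
        fits = list(fits)
        if fits and isinstance(fits[0], ComparisonRow):
            rows = fits
        else:
            raise TypeError("build_comparison_table: expected a power->fits "
                            "mapping or an iterable of ComparisonRow")
    if not rows:
        raise ValueError("build_comparison_table: no rows")

    seen = set()
    for r in rows:
        key = (r.power_w, r.model_id)
        if key in seen:
            raise ValueError(f"duplicate (power, model) pair {key}")
        seen.add(key)

    order = {mid: i for i, mid in enumerate(MODEL_ORDER)}
    rows = sorted(rows, key=lambda r: (order[r.model_id], r.power_w))

    mean_rows = []
    for mid in MODEL_ORDER:
        sub = [r for r in rows if r.model_id == mid]
        if not sub:
            continue
        mean_rows.append(MeanRow(
            model_id=mid,
            r_squared=float(np.mean([r.r_squared for r in sub])),
            sse=float(np.mean([r.sse for r in sub])),
            aard_pct=float(np.mean([r.aard_pct for r in sub])),
            n_powers=len(sub)))
    return ComparisonTable(rows=tuple(rows), mean_rows=tuple(mean_rows))
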