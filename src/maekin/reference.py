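"""Bundled printed summary statistics of the peppermint MAE kinetics study.

These are the published per-power fitted parameters and goodness-of-fit
statistics for total extraction yield (Y, % w/w) and total phenolic content
(TP, g GAE/100 g) at five microwave irradiation powers. They are printed
summaries of fits, not raw kinetic observations (the raw curves were never
tabulated), and serve three purposes here: table-reproduction tests of the
comparison machinery, knots for the k1-vs-power spline optimum, and
realistic parameter ranges for the synthetic-data generator.
"""

from __future__ import annotations

from .gof import ComparisonRow

__all__ = [
    "STUDY_POWERS_W",
    "table_y_rows",
    "table_tp_rows",
    "first_order_k_profile",
]

#: irradiation powers of the study design (W)
STUDY_POWERS_W: tuple[float, ...] = (90.0, 180.0, 360.0, 600.0, 800.0)

# (power_w, params..., r_squared, sse, aard_pct) per model, as printed.
_Y = {
    "first_order": [  # params: k1, c_eq
        (90, 0.419, 37.593, 0.990, 15.182, 4.04),
        (180, 0.750, 38.122, 0.993, 9.329, 2.19),
        (360, 1.187, 37.152, 0.992, 10.466, 2.27),
        (600, 2.431, 36.755, 0.990, 12.237, 2.50),
        (800, 1.680, 38.363, 0.996, 5.862, 1.61),
    ],
    "peleg": [  # params: k2_prime, c_eq
        (90, 1.747, 42.109, 0.974, 39.715, 6.33),
        (180, 0.800, 41.107, 0.982, 24.954, 4.06),
        (360, 0.415, 39.088, 0.986, 17.957, 3.26),
        (600, 0.134, 37.657, 0.996, 4.873, 1.83),
        (800, 0.233, 39.685, 0.997, 3.623, 1.27),
    ],
    "elovich": [  # params: e_rate, a_intercept
        (90, 7.225, 17.882, 0.835, 105.918, 11.05),
        (180, 4.701, 26.218, 0.730, 84.126, 8.14),
        (360, 2.773, 30.470, 0.616, 49.360, 5.08),
        (600, 1.204, 34.209, 0.740, 5.225, 1.68),
        (800, 1.855, 34.109, 0.722, 13.591, 2.60),
    ],
    "power_law": [  # params: b_rate, n_exp
        (90, 20.636, 0.213, 0.897, 156.243, 13.75),
        (180, 27.416, 0.126, 0.929, 100.420, 8.92),
        (360, 30.928, 0.075, 0.958, 53.332, 5.26),
        (600, 34.273, 0.033, 0.996, 5.392, 1.72),
        (800, 34.282, 0.048, 0.989, 14.458, 2.63),
    ],
}

_TP = {
    "first_order": [
        (90, 0.403, 9.236, 0.984, 1.461, 4.90),
        (180, 0.618, 9.466, 0.986, 1.327, 4.40),
        (360, 1.060, 9.356, 0.987, 4.959, 2.86),
        (600, 2.284, 8.744, 0.976, 1.706, 4.08),
        (800, 2.164, 9.202, 0.985, 1.161, 2.95),
    ],
    "peleg": [
        (90, 1.764, 10.307, 0.984, 1.395, 4.67),
        (180, 1.072, 10.357, 0.959, 3.950, 8.25),
        (360, 0.484, 9.892, 0.987, 5.112, 3.03),
        (600, 0.156, 8.991, 0.983, 1.180, 3.38),
        (800, 0.149, 9.430, 0.988, 0.919, 2.86),
    ],
    "elovich": [
        (90, 1.743, 4.425, 0.891, 3.811, 7.03),
        (180, 1.415, 5.797, 0.672, 10.033, 12.94),
        (360, 0.778, 7.452, 0.643, 23.178, 6.00),
        (600, 0.354, 8.000, 0.560, 1.016, 2.47),
        (800, 0.297, 8.542, 0.433, 1.190, 3.39),
    ],
    "power_law": [
        (90, 5.028, 0.215, 0.931, 6.039, 9.73),
        (180, 6.276, 0.153, 0.871, 12.194, 13.92),
        (360, 7.600, 0.083, 0.953, 98.974, 6.22),
        (600, 8.017, 0.041, 0.985, 1.019, 2.48),
        (800, 8.562, 0.032, 0.984, 1.208, 3.42),
    ],
}

_PARAM_NAMES = {
    "first_order": ("k1", "c_eq"),
    "peleg": ("k2_prime", "c_eq"),
    "elovich": ("e_rate", "a_intercept"),
    "power_law": ("b_rate", "n_exp"),
}


def _rows(table: dict) -> list[ComparisonRow]:
    rows = []
    for model_id, entries in table.items():
        p_names = _PARAM_NAMES[model_id]
        for power, p1, p2, r2, sse_val, aard in entries:
            rows.append(ComparisonRow(
                power_w=float(power), model_id=model_id,
                params={p_names[0]: p1, p_names[1]: p2},
                r_squared=r2, sse=sse_val, aard_pct=aard))
    return rows


def table_y_rows() -> list[ComparisonRow]:
    """Published per-power statistics for total extraction yield (Y)."""
    return _rows(_Y)


def table_tp_rows() -> list[ComparisonRow]:
    """Published per-power statistics for total phenolic content (TP)."""
    return _rows(_TP)


def first_order_k_profile(response: str = "TP") -> list[tuple[float, float]]:
    """Published (irradiation power W, first-order k1 min^-1) pairs."""
    table = {"TP": _TP, "Y": _Y}[response.upper()]
    return [(float(p), k) for p, k, *_ in table["first_order"]]
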