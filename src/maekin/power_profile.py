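"""Rate constant vs irradiation power: spline interpolation and optimum.

The first-order rate constant ``k1`` rises with microwave irradiation power
up to a point and then falls (excess energy degrades the analytes), so the
optimal power is the interior maximum of the ``k1(P)`` relationship. The
five experimental powers are interpolated with a natural cubic spline (zero
second derivative at the end knots) and the global maximum is located
analytically: on each cubic piece the derivative is a quadratic whose real
roots, together with the knots, are the only candidate extrema.

Extrapolation outside the measured power range is refused, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "PowerProfile",
    "SplineOptimum",
    "NaturalSpline",
    "build_profile",
    "fit_cubic_spline",
    "find_spline_maximum",
    "profile_report",
]

_KNOT_TOL = 1e-9


@dataclass(frozen=True)
class PowerProfile:
    """Fitted first-order rate constants indexed by irradiation power (W)."""

    powers_w: np.ndarray
    k_values: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.powers_w, dtype=float)
        k = np.asarray(self.k_values, dtype=float)
        object.__setattr__(self, "powers_w", p)
        object.__setattr__(self, "k_values", k)
        if p.ndim != 1 or k.ndim != 1 or len(p) != len(k):
            raise ValueError("PowerProfile: powers_w and k_values must match in length")
        if len(p) < 3:
            raise ValueError("PowerProfile: need at least 3 powers for a spline")
        if not np.all(np.diff(p) > 0):
            raise ValueError("PowerProfile: powers must be strictly increasing")
        if not np.all(k > 0):
            raise ValueError("PowerProfile: rate constants must be > 0")


@dataclass(frozen=True)
class SplineOptimum:
    """Location and value of the global maximum of the k1(P) spline."""

    power_opt_w: float
    k_max: float
    at_knot: bool
    interval_index: int


class NaturalSpline:
    """Interpolating natural cubic spline with piecewise coefficients exposed.

    On piece ``i`` (``x[i] <= P <= x[i+1]``) the spline is
    ``c0*s**3 + c1*s**2 + c2*s + c3`` with ``s = P - x[i]`` and
    ``coefficients[i] = (c0, c1, c2, c3)``.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self._cs = CubicSpline(self.x, self.y, bc_type="natural")

    @property
    def coefficients(self) -> np.ndarray:
        """(n_pieces, 4) array, highest degree first."""
        return self._cs.c.T.copy()

    def __call__(self, p):
        p_arr = np.asarray(p, dtype=float)
        if np.any(p_arr < self.x[0] - _KNOT_TOL) or np.any(p_arr > self.x[-1] + _KNOT_TOL):
            raise ValueError(
                f"power outside the interpolated range [{self.x[0]}, {self.x[-1]}] W; "
                "extrapolation is not supported")
        out = self._cs(np.clip(p_arr, self.x[0], self.x[-1]))
        return float(out) if np.ndim(p) == 0 else out

    def derivative(self, p):
        return self._cs(p, 1)

    def to_dict(self) -> dict:
        return {
            "knots_power_w": self.x.tolist(),
            "knots_k": self.y.tolist(),
            "coefficients": self.coefficients.tolist(),
            "boundary": "natural",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalSpline":
        return cls(np.asarray(d["knots_power_w"]), np.asarray(d["knots_k"]))


def build_profile(fits) -> PowerProfile:
    """Collect (power, k1) pairs from converged first-order fit results.

    ``fits`` maps irradiation power (W) to a first-order
    :class:`~maekin.fitting.FitResult`, or is an iterable of
    ``(power, FitResult)`` pairs. Output is sorted by power; duplicate
    powers are an error.
    """
    if isinstance(fits, Mapping):
        items = list(fits.items())
    else:
        items = list(fits)
    if len(items) < 3:
        raise ValueError("build_profile: need fits for at least 3 powers")
    powers, ks = [], []
    for power, fr in items:
        if fr.model_id != "first_order":
            raise ValueError(f"build_profile: expected first_order fits, got {fr.model_id}")
        if not fr.converged:
            raise ValueError(f"build_profile: fit at {power} W did not converge")
        powers.append(float(power))
        ks.append(float(fr.params.k1))
    order = np.argsort(powers)
    p_sorted = np.asarray(powers)[order]
    if np.any(np.diff(p_sorted) == 0):
        raise ValueError("build_profile: duplicate powers")
    return PowerProfile(powers_w=p_sorted, k_values=np.asarray(ks)[order])


def fit_cubic_spline(profile: PowerProfile) -> NaturalSpline:
    """Interpolating natural cubic spline through the profile's knots."""
    return NaturalSpline(profile.powers_w, profile.k_values)


def find_spline_maximum(spline: NaturalSpline, profile: PowerProfile) -> SplineOptimum:
    """Global maximum of the spline, found analytically per piece.

    Candidates are every knot plus the real roots of each piece's quadratic
    derivative that fall inside the piece. Ties break toward the lowest
    power.
    """
    x = spline.x
    candidates: list[tuple[float, float, int]] = []  # (power, value, piece)
    coeffs = spline.coefficients
    for i in range(len(x) - 1):
        h = x[i + 1] - x[i]
        c0, c1, c2, c3 = coeffs[i]
        candidates.append((x[i], c3, i))
        # derivative 3*c0*s^2 + 2*c1*s + c2 = 0
        for s in np.roots([3 * c0, 2 * c1, c2]):
            if abs(s.imag) < 1e-12 and 0 < s.real < h:
                s_r = s.real
                val = ((c0 * s_r + c1) * s_r + c2) * s_r + c3
                candidates.append((x[i] + s_r, float(val), i))
    candidates.append((x[-1], float(spline.y[-1]), len(x) - 2))

    candidates.sort(key=lambda c: c[0])
    best_p, best_v, best_i = candidates[0]
    for p, v, i in candidates[1:]:
        if v > best_v:  # strict: ties keep the lowest power
            best_p, best_v, best_i = p, v, i
    at_knot = bool(np.any(np.abs(x - best_p) <= _KNOT_TOL * max(1.0, abs(best_p))))
    return SplineOptimum(power_opt_w=float(best_p), k_max=float(best_v),
                         at_knot=at_knot, interval_index=int(best_i))


def profile_report(profile: PowerProfile, optimum: SplineOptimum | None,
                   spline: NaturalSpline | None = None) -> dict:
    """JSON-serializable record of knots, spline coefficients, and optimum."""
    if spline is None:
        spline = fit_cubic_spline(profile)
    return {
        "schema_version": 1,
        "profile": {
            "powers_w": profile.powers_w.tolist(),
            "k_values": profile.k_values.tolist(),
        },
        "spline": spline.to_dict(),
        "optimum": None if optimum is None else {
            "power_opt_w": optimum.power_opt_w,
            "k_max": optimum.k_max,
            "at_knot": optimum.at_knot,
            "interval_index": optimum.interval_index,
        },
    }
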