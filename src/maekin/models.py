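"""Empirical kinetic models for solid–liquid extraction curves.

Four two-parameter model families describe the rise of an extract
concentration ``C_t`` with irradiation time ``t`` (minutes):

* **first-order**  ``C_t = C_eq * (1 - exp(-k1 * t))`` — exponential
  approach to the equilibrium concentration ``C_eq`` at rate ``k1``.
* **Peleg (hyperbolic)**  ``C_t = C_eq * t / (k2' + t)`` — the sorption-
  derived hyperbola; ``k2'`` is the time at half saturation and relates to
  the underlying second-order rate constant via ``k2' = 1 / (C_eq * k2)``.
* **Elovich (logarithmic)**  ``C_t = E * ln(t) + a`` — valid for ``t > 0``;
  ``a`` is the concentration at 1 min.
* **power law**  ``C_t = B * t**n`` with diffusion exponent ``0 < n < 1``,
  typical of diffusion-limited release.

Concentration units (``%``, ``g GAE/100 g``, ...) are carried as opaque
labels throughout the package; no unit conversion is ever applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "FirstOrderParams",
    "PelegParams",
    "ElovichParams",
    "PowerLawParams",
    "ModelSpec",
    "MODEL_ORDER",
    "MODEL_SPECS",
    "PARAM_CLASSES",
    "eval_first_order",
    "eval_peleg",
    "eval_elovich",
    "eval_power_law",
    "evaluate",
    "make_params",
    "second_order_rate",
]

ArrayLike = Union[float, int, np.ndarray, list, tuple]


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FirstOrderParams:
    """Parameters of the first-order uptake model.

    c_eq : equilibrium concentration (response units), > 0
    k1   : rate constant (1/min), > 0
    """

    c_eq: float
    k1: float

    def __post_init__(self) -> None:
        if not (self.c_eq > 0):
            raise ValueError(f"first_order: c_eq must be > 0, got {self.c_eq}")
        if not (self.k1 > 0):
            raise ValueError(f"first_order: k1 must be > 0, got {self.k1}")


@dataclass(frozen=True)
class PelegParams:
    """Parameters of the Peleg hyperbolic model.

    c_eq     : equilibrium concentration (response units), > 0
    k2_prime : half-saturation time (min), > 0
    """

    c_eq: float
    k2_prime: float

    def __post_init__(self) -> None:
        if not (self.c_eq > 0):
            raise ValueError(f"peleg: c_eq must be > 0, got {self.c_eq}")
        if not (self.k2_prime > 0):
            raise ValueError(f"peleg: k2_prime must be > 0, got {self.k2_prime}")


@dataclass(frozen=True)
class ElovichParams:
    """Parameters of the Elovich logarithmic model.

    e_rate      : extraction rate constant (response units per ln-minute), > 0
    a_intercept : concentration at t = 1 min (response units); any finite sign
    """

    e_rate: float
    a_intercept: float

    def __post_init__(self) -> None:
        if not (self.e_rate > 0):
            raise ValueError(f"elovich: e_rate must be > 0, got {self.e_rate}")
        if not math.isfinite(self.a_intercept):
            raise ValueError("elovich: a_intercept must be finite")


@dataclass(frozen=True)
class PowerLawParams:
    """Parameters of the power-law (diffusional) model.

    b_rate : extraction-rate constant (response units per min**n), > 0
    n_exp  : diffusion exponent, strictly inside (0, 1)
    """

    b_rate: float
    n_exp: float

    def __post_init__(self) -> None:
        if not (self.b_rate > 0):
            raise ValueError(f"power_law: b_rate must be > 0, got {self.b_rate}")
        if not (0 < self.n_exp < 1):
            raise ValueError(
                f"power_law: n_exp must lie strictly in (0, 1), got {self.n_exp}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Identity, parameter order, and box bounds of one model family."""

    model_id: str
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.param_names) == len(self.lower) == len(self.upper)):
            raise ValueError("ModelSpec: bounds must match param_names in length")


_TINY = 1e-12

MODEL_ORDER: tuple[str, ...] = ("first_order", "peleg", "elovich", "power_law")

MODEL_SPECS: dict[str, ModelSpec] = {
    "first_order": ModelSpec("first_order", ("c_eq", "k1"), (_TINY, _TINY), (np.inf, np.inf)),
    "peleg": ModelSpec("peleg", ("c_eq", "k2_prime"), (_TINY, _TINY), (np.inf, np.inf)),
    "elovich": ModelSpec("elovich", ("e_rate", "a_intercept"), (_TINY, -np.inf), (np.inf, np.inf)),
    "power_law": ModelSpec("power_law", ("b_rate", "n_exp"), (_TINY, 0.001), (np.inf, 0.999)),
}

PARAM_CLASSES = {
    "first_order": FirstOrderParams,
    "peleg": PelegParams,
    "elovich": ElovichParams,
    "power_law": PowerLawParams,
}


def make_params(model_id: str, values: dict[str, float]):
    """Build the parameter record for ``model_id`` from a name→value mapping."""
    try:
        cls = PARAM_CLASSES[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None
    return cls(**{name: float(values[name]) for name in MODEL_SPECS[model_id].param_names})


# ---------------------------------------------------------------------------
# Forward evaluation
# ---------------------------------------------------------------------------

def _as_time(t: ArrayLike, *, strict_positive: bool, model: str) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if strict_positive:
        if np.any(arr <= 0):
            raise ValueError(f"{model}: time must be strictly positive (log domain)")
    elif np.any(arr < 0):
        raise ValueError(f"{model}: time must be non-negative")
    return arr


def _maybe_scalar(out: np.ndarray, t: ArrayLike):
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def eval_first_order(params: FirstOrderParams, t: ArrayLike):
    """C_eq * (1 - exp(-k1 * t)) for t >= 0; vectorizes over sequences."""
    tt = _as_time(t, strict_positive=False, model="first_order")
    out = params.c_eq * (-np.expm1(-params.k1 * tt))
    return _maybe_scalar(out, t)


def eval_peleg(params: PelegParams, t: ArrayLike):
    """C_eq * t / (k2' + t) for t >= 0."""
    tt = _as_time(t, strict_positive=False, model="peleg")
    out = params.c_eq * tt / (params.k2_prime + tt)
    return _maybe_scalar(out, t)


def eval_elovich(params: ElovichParams, t: ArrayLike):
    """E * ln(t) + a for t > 0 strictly."""
    tt = _as_time(t, strict_positive=True, model="elovich")
    out = params.e_rate * np.log(tt) + params.a_intercept
    return _maybe_scalar(out, t)


def eval_power_law(params: PowerLawParams, t: ArrayLike):
    """B * t**n for t >= 0; since 0 < n < 1, the value at t = 0 is 0."""
    tt = _as_time(t, strict_positive=False, model="power_law")
    out = params.b_rate * np.power(tt, params.n_exp)
    return _maybe_scalar(out, t)


_EVALUATORS = {
    "first_order": eval_first_order,
    "peleg": eval_peleg,
    "elovich": eval_elovich,
    "power_law": eval_power_law,
}


def evaluate(model_id: str, params, t: ArrayLike):
    """Evaluate any model family by id; ``params`` is its record or a dict."""
    if isinstance(params, dict):
        params = make_params(model_id, params)
    try:
        fn = _EVALUATORS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None
    return fn(params, t)


def second_order_rate(params: PelegParams) -> float:
    """Second-order rate constant k2 = 1 / (C_eq * k2') behind the Peleg form.

    The hyperbola is the closed-form solution of the second-order uptake law
    dC/dt = k2 * (C_eq - C)^2; re-parameterizing with k2' = 1/(C_eq*k2) gives
    the half-saturation form used for fitting.
    """
    return 1.0 / (params.c_eq * params.k2_prime)
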