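"""Synthetic extraction-kinetics data with the structure the analysis assumes.

The study's raw curves were never published as numbers, so testing the
fitting, comparison, and power-profile stages requires simulated datasets.
The generator forward-simulates any of the four kinetic model families on
the study's sampling schedule (1, 2, 3, 4, 5, 7.5, 10, 15, 20, 25, 30 min),
optionally applies a multiplicative exponential degradation after an onset
time (emulating the post-15-min decline of yield and phenolics seen at high
irradiation power), and adds i.i.d. Gaussian observation noise. A series
generator emulates the five-power experimental design, each power sharing
the equilibrium concentration but carrying its own rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .fitting import KineticDataset
from .models import MODEL_SPECS, evaluate, make_params

__all__ = [
    "PAPER_SCHEDULE_MIN",
    "SyntheticConfig",
    "PowerSeriesConfig",
    "generate_curve",
    "generate_power_series",
]

#: the study's sampling times in minutes
PAPER_SCHEDULE_MIN: tuple[float, ...] = (1, 2, 3, 4, 5, 7.5, 10, 15, 20, 25, 30)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SyntheticConfig:
    """One simulated extraction curve.

    noise_sd is the standard deviation of additive Gaussian noise, in
    response units; with ``noise_relative=True`` it is interpreted as a
    fraction of the model's equilibrium concentration ``c_eq`` (only
    meaningful for the first-order and Peleg families). Degradation, when
    configured, multiplies the noiseless curve by
    ``exp(-degradation_rate * (t - t_d))`` for ``t > t_d``.
    """

    model_id: str
    params: Mapping[str, float]
    times: Sequence[float] = PAPER_SCHEDULE_MIN
    noise_sd: float = 0.0
    noise_relative: bool = False
    degradation_onset_min: Optional[float] = None
    degradation_rate: float = 0.0
    seed: int = 0
    response_label: str = "TP"
    power_w: Optional[float] = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_SPECS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.degradation_rate < 0:
            raise ValueError("degradation_rate must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if self.degradation_onset_min is not None:
            if not (t[0] <= self.degradation_onset_min <= t[-1]):
                raise ValueError("degradation_onset_min must lie within the schedule span")
        if self.noise_relative and "c_eq" not in self.params:
            raise ValueError("relative noise requires a model with a c_eq parameter")

    @property
    def absolute_noise_sd(self) -> float:
        if self.noise_relative:
            return self.noise_sd * float(self.params["c_eq"])
        return self.noise_sd


def _degradation_factor(t: np.ndarray, onset: Optional[float], rate: float) -> np.ndarray:
    if onset is None or rate == 0.0:
        return np.ones_like(t)
    return np.where(t <= onset, 1.0, np.exp(-rate * (t - onset)))


def generate_curve(config: SyntheticConfig) -> KineticDataset:
    """Simulate one curve: model(t) * degradation(t) + Gaussian noise.

    Non-positive draws are redrawn point-wise up to 100 times (observed
    concentrations are strictly positive); persistently non-positive draws
    (noise too large for the signal) raise. Deterministic for a fixed seed.
    """
    t = np.asarray(config.times, dtype=float)
    params = make_params(config.model_id, dict(config.params))
    clean = np.asarray(evaluate(config.model_id, params, t), dtype=float)
    clean = clean * _degradation_factor(t, config.degradation_onset_min,
                                        config.degradation_rate)
    rng = np.random.default_rng(config.seed)
    sd = config.absolute_noise_sd
    values = clean + (rng.normal(0.0, sd, size=t.shape) if sd > 0 else 0.0)
    for _ in range(_MAX_REDRAWS):
        bad = values <= 0
        if not np.any(bad):
            break
        values[bad] = clean[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
    else:
        raise ValueError("generate_curve: could not draw positive values in "
                         f"{_MAX_REDRAWS} attempts; noise_sd too large")
    return KineticDataset(times=t, values=values,
                          response_label=config.response_label,
                          power_w=config.power_w, units=config.units)


@dataclass(frozen=True)
class PowerSeriesConfig:
    """The five-power design: one curve per power, shared c_eq and schedule.

    ``k_of_power`` maps irradiation power (W) to the first-order rate
    constant used at that power. Per-power seeds derive from ``seed`` plus
    the power's index in ascending power order, so each power's noise is
    reproducible and independent of the order the powers are listed in.
    """

    powers_w: Sequence[float]
    k_of_power: Mapping[float, float]
    c_eq: float
    times: Sequence[float] = PAPER_SCHEDULE_MIN
    noise_sd: float = 0.0
    noise_relative: bool = False
    degradation_onset_min: Optional[float] = None
    degradation_rate: float = 0.0
    seed: int = 0
    response_label: str = "TP"
    units: str = ""

    def __post_init__(self) -> None:
        if self.c_eq <= 0:
            raise ValueError("c_eq must be > 0")
        missing = [p for p in self.powers_w if p not in self.k_of_power]
        if missing:
            raise ValueError(f"k_of_power missing entries for powers {missing}")


def generate_power_series(config: PowerSeriesConfig) -> list[KineticDataset]:
    """One dataset per power, in the order the powers are given."""
    rank = {p: i for i, p in enumerate(sorted(set(config.powers_w)))}
    out = []
    for power in config.powers_w:
        curve_cfg = SyntheticConfig(
            model_id="first_order",
            params={"c_eq": config.c_eq, "k1": config.k_of_power[power]},
            times=config.times,
            noise_sd=config.noise_sd,
            noise_relative=config.noise_relative,
            degradation_onset_min=config.degradation_onset_min,
            degradation_rate=config.degradation_rate,
            seed=config.seed + rank[power],
            response_label=config.response_label,
            power_w=float(power),
            units=config.units,
        )
        out.append(generate_curve(curve_cfg))
    return out
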