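# maekin — empirical kinetics of microwave-assisted extraction

`maekin` models time–yield curves from microwave-assisted extraction (MAE)
of plant bioactives — total extraction yield (Y), total phenolic content
(TP, g GAE/100 g) — and locates the microwave irradiation power that
maximizes the extraction rate. It is aimed at phytochemical process
engineers who measure a response at a handful of extraction times per
power setting and want a defensible, reproducible model comparison.

## The models and statistics

Four empirical families are fitted to each curve `C_t` vs time `t` (min)
by non-linearized least squares (bounded trust-region solver of the
Levenberg–Marquardt class; the Elovich model, linear in its parameters, is
solved in closed form):

| model | equation | parameters |
|---|---|---|
| first-order | `C_t = C_eq (1 − e^(−k₁ t))` | `C_eq`, `k₁` (min⁻¹) |
| Peleg hyperbolic | `C_t = C_eq t / (k₂′ + t)` | `C_eq`, `k₂′` (min); `k₂ = 1/(C_eq k₂′)` |
| Elovich | `C_t = E ln t + a` | `E`, `a` |
| power law | `C_t = B tⁿ` | `B`, `n` ∈ (0, 1) |

Fits are scored with `SSer = Σ(obs − pred)²`, `R² = 1 − SSer/SStot`, and
`AARD = (100/N) Σ |obs − pred|/obs` (%). A comparison table collects the
statistics per (power, model) with per-model mean rows.

The fitted first-order rate constants `k₁(P)` across irradiation powers
`P` are interpolated with a natural cubic spline and the optimal power is
the spline's global maximum, found analytically on each cubic piece (the
derivative is a quadratic).

A synthetic-data module generates first-order (or any family) curves on
the standard 11-point sampling schedule (1–30 min) with additive Gaussian
noise and an optional post-onset exponential degradation, so every stage
is testable without unpublished raw curves. The published per-power
parameters and statistics are bundled (`maekin.reference`) as printed
summaries.

## Worked example

```python
import numpy as np
from maekin import (PowerProfile, find_spline_maximum, fit_cubic_spline,
                    reference)

pairs = reference.first_order_k_profile("TP")   # published (P, k1) pairs
profile = PowerProfile(powers_w=np.array([p for p, _ in pairs]),
                       k_values=np.array([k for _, k in pairs]))
opt = find_spline_maximum(fit_cubic_spline(profile), profile)
print(opt)
```

prints

```
SplineOptimum(power_opt_w=664.7629231797393, k_max=2.363636231043717,
              at_knot=False, interval_index=3)
```

i.e. the spline through the five measured rate constants (0.403 … 2.284
min⁻¹ at 90–800 W) peaks between the 600 W and 800 W knots: the predicted
optimal irradiation power is ≈665 W with a predicted rate constant of
≈2.36 min⁻¹, slightly above the best measured knot (2.28 min⁻¹ at 600 W).

The same from the shell, plus a full simulate→fit→report pipeline:

```bash
maekin power-opt --fixture tp -o optimum.json
maekin simulate -o sim.csv --seed 1          # five-power synthetic study
maekin fit -i sim.csv -o fits.json --seed 1
maekin report --fits fits.json --optimum optimum.json -o report.csv
maekin compare --fixture tp -o table.csv     # published comparison table
```

`table.csv` ends each model block with a `Mean` row; for TP the
first-order row reads `0.984, 2.123, 3.84` (R², SSer, AARD %) — the
lowest error statistics of the four families, which is why `k₁` from the
first-order model drives the power optimization.

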